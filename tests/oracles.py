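"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written with plain Python loops and ``math`` only — no
numpy, no imports from the package under test — so agreement between these
and the vectorised implementations is evidence, not tautology.
"""

from __future__ import annotations

import itertools
import math


def tally_spectrum(counts):
    """Frequency-of-frequencies by explicit recount."""
    f = {}
    for y in counts:
        f[y] = f.get(y, 0) + 1
    return f


def _get(f, r):
    return f.get(r, 0)


def chao1_loop(f):
    f1, f2 = _get(f, 1), _get(f, 2)
    if f1 == 0:
        return 0.0
    if f2 == 0:
        return f1 * (f1 - 1) / 2.0  # bias-corrected fallback
    return f1 * f1 / (2.0 * f2)


def chao2_loop(f):
    f1, f2 = _get(f, 1), _get(f, 2)
    return f1 * (f1 - 1) / (2.0 * (f2 + 1))


def ichao1_loop(f):
    f1, f2, f3, f4 = (_get(f, r) for r in (1, 2, 3, 4))
    if f1 == 0:
        return 0.0
    base = f1 * (f1 - 1) / 2.0 if f2 == 0 else f1 * f1 / (2.0 * f2)
    corr = 0.0
    if f4 > 0:
        corr = (f3 / (4.0 * f4)) * max(f1 - f2 * f3 / (2.0 * f4), 0.0)
    return base + corr


def medial_loop(f, exact=False):
    f1, f2 = _get(f, 1), _get(f, 2)
    value = f1 * (f1 - 1) / (f2 + 1.0)
    if exact:
        N = sum(r * fr for r, fr in f.items())
        value *= (N - 1) / N
    return value


def pythagorean_loop(f, mean_type, degree, u):
    """Returns NaN for the degenerate (undefined) case."""
    f1 = _get(f, 1)
    if f1 == 0:
        return 0.0
    vals = [float(_get(f, r)) for r in range(2, degree + 1)]
    if mean_type == "arithmetic":
        c = sum(vals) / len(vals)
    elif any(v == 0 for v in vals):
        c = 0.0
    elif mean_type == "geometric":
        prod = 1.0
        for v in vals:
            prod *= v
        c = prod ** (1.0 / len(vals))
    else:
        c = len(vals) / sum(1.0 / v for v in vals)
    if c == 0.0:
        return math.nan
    return u * f1 * f1 / c


def h6_loop(f):
    return pythagorean_loop(f, "harmonic", 6, 0.6)


def good_turing_loop(f, r):
    return (r + 1) * _get(f, r + 1) / _get(f, r)


def coverage_loop(f):
    N = sum(r * fr for r, fr in f.items())
    return 1.0 - _get(f, 1) / N


def prob_all_detected_enumerate(p, N):
    """Exhaustive enumeration of every length-N outcome sequence."""
    G = len(p)
    total = 0.0
    for outcome in itertools.product(range(G), repeat=N):
        if len(set(outcome)) == G:
            prob = 1.0
            for gene in outcome:
                prob *= p[gene]
            total += prob
    return total


def expected_detected_loop(p, depth):
    return sum(1.0 - math.exp(-depth * pi) for pi in p)


def extra_chao_loop(N, g, f1, f2, f0_hat, psi):
    G_hat = g + f0_hat
    ratio = f0_hat / (G_hat * (1.0 - psi))
    if f1 == 0:
        return 0.0
    if ratio <= 1.0:
        return math.nan
    return N * (f1 / (2.0 * f2)) * math.log(ratio)


def extra_h6_loop(N, g, f1, h6_hat, psi):
    G_hat = g + h6_hat
    if f1 == 0:
        return 0.0
    ratio = h6_hat / (G_hat * (1.0 - psi))
    if ratio <= 1.0:
        return math.nan
    return N * (h6_hat / f1) * math.log(ratio)


def random_spectra(rng, n, max_r=10, max_f=50):
    """Random sparse spectra as dicts, for oracle-agreement sweeps."""
    out = []
    for _ in range(n):
        f = {}
        for r in range(1, max_r + 1):
            fr = int(rng.integers(0, max_f + 1))
            if fr and rng.random() < 0.8:
                f[r] = fr
        if not f:
            f = {1: 1}
        out.append(f)
    return out
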