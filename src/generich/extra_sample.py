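"""Extra sequencing depth needed to observe a proportion of the missing genes.

Given a sample of depth ``N`` with ``g`` detected genes and an estimate
``f0_hat`` of the undetected ones, how many additional tags ``m`` raise the
detected count to ``g + psi * f0_hat`` for a target proportion
``0 < psi < 1``?  Two closed forms are provided (natural logarithm):

    Chao-style:   m_psi  = N * (f1 / (2 f2)) * ln( f0_hat / (G_hat (1 - psi)) )
    h6-style:     m'_psi = N * (h6 / f1)     * ln( h6     / (G_hat (1 - psi)) )

with ``G_hat = g + f0_hat``.  Both are subject to the positivity condition
``f0_hat / (G_hat (1 - psi)) > 1``; when it fails, the target proportion is
already within reach of the current depth and no extra sample is needed (or
the estimate is too small to say).  Both return 0 on a complete sample
(``f1 = 0``, hence ``f0_hat = 0``) and diverge as ``psi -> 1``: no finite
depth guarantees that nothing is missing.

Extra-sample methods are compared by the weighted squared error

    WSE = ( (g + psi * f0_hat - E[G | N + m]) / f0_hat )^2

the squared gap between the predicted and the expected detected-gene totals
after the extension, in units of the estimated deficit.  ``E[G | N + m]``
is computed by Poissonization when the truth probabilities are known and by
bootstrap averaging otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .estimators import chao1, h6
from .resampling import BootstrapConfig, bootstrap_sample, replicate_rng
from .spectrum_io import CountVector, FrequencySpectrum

__all__ = [
    "ExtraSampleEstimate",
    "extra_sample_chao",
    "extra_sample_h6",
    "expected_genes_detected",
    "solve_extra_sample_exact",
    "weighted_squared_error",
    "compare_extra_sample_estimators",
]


@dataclass(frozen=True)
class ExtraSampleEstimate:
    """Extra tags needed to reach a target detection proportion ``psi``.

    ``m_extra`` is NaN when the positivity condition failed (the target is
    already within reach) or when the formula was degenerate (``f2 = 0`` in
    the Chao form).
    """

    psi: float
    m_extra: float
    method: str
    condition_met: bool
    degenerate: bool = False


def _check_psi(psi: float) -> float:
    psi = float(psi)
    if not 0.0 < psi < 1.0:
        raise ValueError("psi must be strictly between 0 and 1")
    return psi


def extra_sample_chao(
    spec: FrequencySpectrum, f0_hat: float, psi: float
) -> ExtraSampleEstimate:
    """Chao-style extra sample size (pairs naturally with Chao-family f0_hat)."""
    psi = _check_psi(psi)
    if spec.N < 1:
        raise ValueError("sample size N must be >= 1")
    f1, f2 = spec[1], spec[2]
    if f1 == 0:
        return ExtraSampleEstimate(psi, 0.0, "chao", True)
    G_hat = spec.g + f0_hat
    ratio = f0_hat / (G_hat * (1.0 - psi))
    if not ratio > 1.0:
        return ExtraSampleEstimate(psi, math.nan, "chao", False)
    if f2 == 0:
        return ExtraSampleEstimate(psi, math.nan, "chao", True, degenerate=True)
    m = spec.N * (f1 / (2.0 * f2)) * math.log(ratio)
    return ExtraSampleEstimate(psi, m, "chao", True)


def extra_sample_h6(
    spec: FrequencySpectrum, h6_hat: float, psi: float
) -> ExtraSampleEstimate:
    """h6-style extra sample size; ``h6_hat`` should come from the h6 estimator."""
    psi = _check_psi(psi)
    if spec.N < 1:
        raise ValueError("sample size N must be >= 1")
    f1 = spec[1]
    if f1 == 0:
        if h6_hat > 0:
            raise ValueError("inconsistent inputs: f1 = 0 forces h6_hat = 0")
        return ExtraSampleEstimate(psi, 0.0, "h6", True)
    G_hat = spec.g + h6_hat
    ratio = h6_hat / (G_hat * (1.0 - psi))
    if not ratio > 1.0:
        return ExtraSampleEstimate(psi, math.nan, "h6", False)
    m = spec.N * (h6_hat / f1) * math.log(ratio)
    return ExtraSampleEstimate(psi, m, "h6", True)


def expected_genes_detected(p: np.ndarray, depth: float) -> float:
    """Poissonized expected number of detected genes at a given depth:
    ``sum_i 1 - exp(-depth * p_i)``."""
    p = np.asarray(p, dtype=float)
    if depth < 0:
        raise ValueError("depth must be >= 0")
    return float(np.sum(-np.expm1(-depth * p)))


def solve_extra_sample_exact(
    p: np.ndarray, N: float, target_genes: float, max_factor: float = 1e6
) -> float:
    """Numerically invert the expected-detection curve: the smallest ``m``
    with ``E[G | N + m] = target_genes`` under the truth ``p``.

    Serves as the oracle extra-sample method: plugged into the comparison
    harness it realises its prediction by construction.  Raises if the
    target is unreachable below ``N * max_factor`` extra tags.
    """
    p = np.asarray(p, dtype=float)
    if expected_genes_detected(p, N) >= target_genes:
        return 0.0
    hi = float(N)
    while expected_genes_detected(p, N + hi) < target_genes:
        hi *= 2.0
        if hi > N * max_factor:
            raise ValueError("target detection level unreachable at any sane depth")
    return float(brentq(lambda m: expected_genes_detected(p, N + m) - target_genes, 0.0, hi))


def weighted_squared_error(
    predicted_total: float, expected_total: float, f0_hat: float
) -> float:
    """``((predicted_total - expected_total) / f0_hat)^2``.

    ``predicted_total`` is the method's promised detected-gene count
    ``g + psi * f0_hat``; ``expected_total`` is ``E[G | N + m]`` under the
    reference distribution.  The weight ``1/f0_hat^2`` expresses the gap in
    units of the estimated deficit and is undefined for ``f0_hat = 0``.
    """
    if not f0_hat > 0:
        raise ValueError("weighted squared error is undefined for f0_hat <= 0")
    return float(((predicted_total - expected_total) / f0_hat) ** 2)


# Default probe depths for the method comparison, as fractions of the
# reference depth.  The range is chosen so the expected fraction of missing
# genes in a replicate spans roughly 3%-40% for the default synthetic
# reference: deep enough that the spectrum is informative, shallow enough
# that the extra-sample question is live (the positivity condition fails by
# design once almost nothing is missing).
DEPTH_FRACTION_RANGE = (0.001, 0.02)

# A comparison method maps (replicate spectrum, psi, true_f0) to
# (f0_hat, extra_fn); NaN f0_hat marks a degenerate replicate.  The default
# methods ignore the truth; an oracle method injected in tests may use it.
_DEFAULT_METHODS: Mapping[str, Callable] = {
    "chao": lambda spec, psi, true_f0: (chao1(spec).f0_hat, extra_sample_chao),
    "h6": lambda spec, psi, true_f0: (h6(spec).f0_hat, extra_sample_h6),
}


def compare_extra_sample_estimators(
    complete: CountVector,
    psis: Sequence[float] = (0.95,),
    config: BootstrapConfig | None = None,
    methods: Mapping[str, Callable] | None = None,
    paired: bool = True,
) -> pd.DataFrame:
    """Score extra-sample methods by weighted squared error on bootstrap
    subsamples of a complete reference.

    Each replicate draws a depth ``N_i`` uniformly on ``[n_min, n_max]``
    and a subsample of the reference; each method computes its ``f0_hat``
    and extra depth ``m``, and the realised expectation
    ``E[G | N_i + m]`` is evaluated by Poissonization under the reference's
    empirical probabilities.  Returns one row per (method, psi) with mean
    and median WSE plus counts of replicates where the positivity condition
    failed or the estimator was degenerate.

    When ``config`` is omitted the probe depths default to
    ``DEPTH_FRACTION_RANGE`` times the reference depth (shallow subsamples,
    where missing genes are plentiful); at depths near completeness the
    positivity condition fails by design and replicates are only counted.

    With ``paired=True`` (default) the WSE summaries are restricted, per
    psi, to replicates where *every* method produced a value: the
    positivity condition tends to fail on different replicates for
    different methods (a method whose f0_hat is biased low gives up
    earliest), and unpaired summaries would confound a method's accuracy
    with the depths at which it happens to answer.  Condition-failure and
    degeneracy counts always refer to all replicates.

    ``methods`` may be overridden; each entry maps
    ``(spectrum, psi, true_f0)`` to ``(f0_hat, extra_fn)`` where
    ``extra_fn(spec, f0_hat, psi)`` returns an :class:`ExtraSampleEstimate`
    — this is how an oracle method is injected in tests.
    """
    if methods is None:
        methods = _DEFAULT_METHODS
    if config is None:
        lo, hi = DEPTH_FRACTION_RANGE
        config = BootstrapConfig(
            n_min=max(1, round(lo * complete.N)), n_max=round(hi * complete.N)
        )
    psis = [_check_psi(psi) for psi in psis]
    n_max = complete.N if config.n_max is None else config.n_max
    if n_max > complete.N:
        raise ValueError("n_max exceeds the reference depth")
    p_ref = complete.counts / complete.N
    wse: dict[tuple[str, float], dict[int, float]] = {
        (m, psi): {} for m in methods for psi in psis
    }
    n_condition_failed = dict.fromkeys(wse, 0)
    n_degenerate = dict.fromkeys(wse, 0)
    for i in range(config.B):
        rng = replicate_rng(config.seed, i)
        N_i = int(rng.integers(config.n_min, n_max + 1))
        rep_spec, true_f0 = bootstrap_sample(complete, N_i, config.distribution, rng=rng)
        g_i = rep_spec.g
        for name, method in methods.items():
            for psi in psis:
                key = (name, psi)
                f0_hat, extra_fn = method(rep_spec, psi, true_f0)
                if math.isnan(f0_hat) or f0_hat <= 0:
                    n_degenerate[key] += 1
                    continue
                extra = extra_fn(rep_spec, f0_hat, psi)
                if not extra.condition_met:
                    n_condition_failed[key] += 1
                    continue
                if extra.degenerate or math.isnan(extra.m_extra):
                    n_degenerate[key] += 1
                    continue
                expected = expected_genes_detected(p_ref, N_i + extra.m_extra)
                wse[key][i] = weighted_squared_error(
                    g_i + psi * f0_hat, expected, f0_hat
                )
    rows = []
    for psi in psis:
        if paired:
            common = set.intersection(
                *(set(wse[(name, psi)]) for name in methods)
            ) if methods else set()
        for name in methods:
            values = wse[(name, psi)]
            keep = sorted(common) if paired else sorted(values)
            arr = np.asarray([values[i] for i in keep])
            rows.append(
                {
                    "method": name,
                    "psi": psi,
                    "n_used": int(arr.size),
                    "n_condition_failed": n_condition_failed[(name, psi)],
                    "n_degenerate": n_degenerate[(name, psi)],
                    "wse_mean": float(arr.mean()) if arr.size else math.nan,
                    "wse_median": float(np.median(arr)) if arr.size else math.nan,
                }
            )
    return pd.DataFrame(rows)
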