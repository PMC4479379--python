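"""Closed-form nonparametric estimators of the number of undetected genes.

All estimators consume only the frequency-of-frequencies spectrum and return
a :class:`~generich.spectrum_io.RichnessEstimate`.  They share three
conventions:

* a complete sample (``f1 = 0``) yields exactly 0 missing genes;
* estimates are kept at full floating precision — rounding to integers
  happens only in reports;
* a zero denominator sets ``degenerate=True``.  Chao1 falls back to the
  bias-corrected Chao2 form (always finite); the Pythagorean-mean family,
  including h6, has no standard correction and returns NaN instead.

The Pythagorean family generalises Chao1's ``f1^2 / (2 f2)`` by replacing
the doubleton count with a measure of central tendency of ``f2..f_degree``:

    f0_hat = u * f1^2 / c(f2, ..., f_degree)

with ``c`` the arithmetic, geometric or harmonic mean and ``u`` a scalar
constant.  RNA-seq depths are large enough that ``f_r`` for ``r`` up to 10
is usually positive, so these higher classes carry usable information that
ecology-scale samples lack.  The harmonic estimator of degree 6,

    h6 = (6/10) * f1^2 / H(f2, ..., f6),   H = 5 / sum_{r=2..6} 1/f_r,

is the member selected by bootstrap evaluation against known-truth
subsamples (see :mod:`generich.resampling`) and is the default estimator
throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .spectrum_io import FrequencySpectrum, RichnessEstimate

__all__ = [
    "EstimatorSpec",
    "chao1",
    "chao2_corrected",
    "ichao1",
    "medial",
    "naive",
    "pythagorean_family",
    "h6",
    "good_turing_adjusted_count",
    "good_coverage",
    "percent_undetected",
    "get_estimator",
    "ESTIMATORS",
]

_MEANS = ("arithmetic", "geometric", "harmonic")


@dataclass(frozen=True)
class EstimatorSpec:
    """Identifies one member of the estimator families.

    ``mean_type``, ``degree`` (highest ``f_r`` used, 3..10) and ``u`` are
    meaningful only for the ``pythagorean`` family; ``h6`` is shorthand for
    ``pythagorean(harmonic, degree=6, u=6/10)``.
    """

    family: str
    mean_type: str = "harmonic"
    degree: int = 6
    u: float = 0.6

    def __post_init__(self) -> None:
        if self.family not in ("chao1", "chao2", "ichao1", "medial", "naive", "pythagorean", "h6"):
            raise ValueError(f"unknown estimator family {self.family!r}")
        if self.family == "pythagorean":
            if self.mean_type not in _MEANS:
                raise ValueError(f"mean_type must be one of {_MEANS}")
            if not 3 <= int(self.degree) <= 10:
                raise ValueError("degree must be in 3..10")
            if not self.u > 0:
                raise ValueError("u must be positive")

    def build(self):
        """Return the estimator callable ``spectrum -> RichnessEstimate``."""
        if self.family == "pythagorean":
            mean, degree, u = self.mean_type, int(self.degree), float(self.u)
            def est(spec: FrequencySpectrum) -> RichnessEstimate:
                return pythagorean_family(spec, mean, degree, u)
            est.__name__ = f"pythagorean:{mean}:{degree}:{u:g}"
            return est
        return ESTIMATORS[self.family]


def _estimate(spec: FrequencySpectrum, name: str, f0: float, degenerate: bool = False) -> RichnessEstimate:
    return RichnessEstimate(name, float(f0), spec.g, spec.N, degenerate=degenerate)


def chao1(spec: FrequencySpectrum) -> RichnessEstimate:
    """Chao1 lower bound, ``f1^2 / (2 f2)``.

    With ``f2 = 0`` and ``f1 > 0`` the raw form is undefined; the
    bias-corrected Chao2 form ``f1 (f1-1) / (2 (f2+1))`` is returned with
    ``degenerate=True``, following common ecological-software practice.
    """
    f1, f2 = spec[1], spec[2]
    if f1 == 0:
        return _estimate(spec, "chao1", 0.0)
    if f2 == 0:
        return _estimate(spec, "chao1", f1 * (f1 - 1) / 2.0, degenerate=True)
    return _estimate(spec, "chao1", f1 * f1 / (2.0 * f2))


def chao2_corrected(spec: FrequencySpectrum) -> RichnessEstimate:
    """Bias-corrected Chao2 form, ``f1 (f1-1) / (2 (f2+1))``; always finite."""
    f1, f2 = spec[1], spec[2]
    return _estimate(spec, "chao2", f1 * (f1 - 1) / (2.0 * (f2 + 1)))


def ichao1(spec: FrequencySpectrum) -> RichnessEstimate:
    """Improved Chao1, adding information from ``f3`` and ``f4``:

    ``f1^2/(2 f2) + (f3/(4 f4)) * max(f1 - f2 f3 / (2 f4), 0)``.

    The correction term is non-negative, so iChao1 >= Chao1 wherever both
    are defined.  Zero denominators: ``f2 = 0`` makes the base term fall
    back as in :func:`chao1`; ``f4 = 0`` with ``f3 > 0`` drops the
    correction term (reverting to the Chao1 lower bound); both flag the
    result degenerate.
    """
    f1, f2, f3, f4 = spec[1], spec[2], spec[3], spec[4]
    if f1 == 0:
        return _estimate(spec, "ichao1", 0.0)
    degenerate = False
    if f2 > 0:
        base = f1 * f1 / (2.0 * f2)
    else:
        base = f1 * (f1 - 1) / 2.0
        degenerate = True
    if f4 > 0:
        corr = (f3 / (4.0 * f4)) * max(f1 - f2 * f3 / (2.0 * f4), 0.0)
    else:
        corr = 0.0
        degenerate = degenerate or f3 > 0
    return _estimate(spec, "ichao1", base + corr, degenerate=degenerate)


def medial(spec: FrequencySpectrum, exact: bool = False) -> RichnessEstimate:
    """Medial estimator, ``f1 (f1-1) / (f2+1)``; always finite.

    The exact form carries a factor ``(N-1)/N`` that is irrelevant at
    RNA-seq depths (millions of tags) and is applied only when
    ``exact=True``.
    """
    f1, f2 = spec[1], spec[2]
    f0 = f1 * (f1 - 1) / (f2 + 1.0)
    if exact:
        N = spec.N
        if N < 1:
            raise ValueError("exact Medial needs a sample size N >= 1")
        f0 *= (N - 1) / N
    return _estimate(spec, "medial", f0)


def naive(spec: FrequencySpectrum) -> RichnessEstimate:
    """The do-nothing estimator: f0_hat = 0 for any sample (G assumed = g)."""
    return _estimate(spec, "naive", 0.0)


def pythagorean_family(
    spec: FrequencySpectrum, mean_type: str, degree: int, u: float
) -> RichnessEstimate:
    """Generalised Chao-type estimator ``u * f1^2 / c(f2..f_degree)``.

    ``c`` is the arithmetic, geometric or harmonic mean of the frequency
    classes ``f2`` through ``f_degree``.  When ``c`` is zero or undefined
    (any ``f_r = 0`` for the geometric/harmonic means) the estimate is
    returned as NaN with ``degenerate=True``: no standard correction exists
    and silently substituting one would bias the downstream bootstrap.
    """
    if mean_type not in _MEANS:
        raise ValueError(f"mean_type must be one of {_MEANS}")
    if not 3 <= int(degree) <= 10:
        raise ValueError("degree must be in 3..10")
    if not u > 0:
        raise ValueError("u must be positive")
    name = f"pythagorean:{mean_type}:{int(degree)}:{u:g}"
    f1 = spec[1]
    if f1 == 0:
        return _estimate(spec, name, 0.0)
    vals = np.array([spec[r] for r in range(2, int(degree) + 1)], dtype=float)
    if mean_type == "arithmetic":
        c = float(vals.mean())
    elif (vals == 0).any():
        c = 0.0
    elif mean_type == "geometric":
        c = float(np.exp(np.mean(np.log(vals))))
    else:  # harmonic
        c = float(vals.size / np.sum(1.0 / vals))
    if c == 0.0:
        return _estimate(spec, name, math.nan, degenerate=True)
    return _estimate(spec, name, u * f1 * f1 / c)


def h6(spec: FrequencySpectrum) -> RichnessEstimate:
    """Harmonic estimator of degree 6, ``(6/10) f1^2 / H(f2..f6)``.

    ``H = 5 / sum_{r=2..6} 1/f_r``.  Defined via the Pythagorean family so
    the two entry points are bit-identical; any of ``f2..f6`` equal to zero
    makes the estimate NaN with ``degenerate=True`` (negligibly probable at
    realistic RNA-seq depths).
    """
    return replace(pythagorean_family(spec, "harmonic", 6, 0.6), estimator_name="h6")


def good_turing_adjusted_count(spec: FrequencySpectrum, r: int) -> float:
    """Good-Turing adjusted count ``r* = (r+1) f_{r+1} / f_r``.

    The expected relative frequency of a gene seen ``r`` times is better
    estimated by ``r*/N`` than by ``r/N`` when the number of classes is
    unknown.  Undefined when ``f_r = 0``.
    """
    r = int(r)
    fr = spec[r]
    if fr == 0:
        raise ValueError(f"undefined adjusted count: f_{r} = 0")
    return (r + 1) * spec[r + 1] / fr


def good_coverage(spec: FrequencySpectrum) -> float:
    """Good's sample coverage, ``1 - f1/N``: the estimated probability mass
    of the population already represented in the sample."""
    N = spec.N
    if N < 1:
        raise ValueError("coverage needs a sample size N >= 1")
    return 1.0 - spec[1] / N


def percent_undetected(f0_hat: float, g: int) -> float:
    """Estimated percentage of expressed genes missing: ``100 f0_hat / (g + f0_hat)``."""
    if not f0_hat >= 0:
        raise ValueError("f0_hat must be >= 0")
    if g < 1:
        raise ValueError("g must be >= 1")
    return 100.0 * f0_hat / (g + f0_hat)


ESTIMATORS = {
    "chao1": chao1,
    "chao2": chao2_corrected,
    "ichao1": ichao1,
    "medial": medial,
    "naive": naive,
    "h6": h6,
}


def get_estimator(name: str):
    """Resolve an estimator name to a callable ``spectrum -> RichnessEstimate``.

    Accepts ``chao1 | chao2 | ichao1 | medial | naive | h6`` or the family
    syntax ``pythagorean:<mean>:<degree>:<u>`` (e.g. ``pythagorean:harmonic:6:0.6``).
    """
    name = name.strip()
    if name in ESTIMATORS:
        return ESTIMATORS[name]
    if name.startswith("pythagorean"):
        parts = name.split(":")
        if len(parts) != 4:
            raise ValueError("expected pythagorean:<mean>:<degree>:<u>")
        return EstimatorSpec("pythagorean", parts[1], int(parts[2]), float(parts[3])).build()
    raise ValueError(
        f"unknown estimator {name!r}; choose from {', '.join(ESTIMATORS)} "
        "or pythagorean:<mean>:<degree>:<u>"
    )
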