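"""Parametric bootstrap machinery: standard errors, confidence intervals,
and the estimator-selection harness.

A sample whose spectrum satisfies the completeness criterion (``f1 = 0``)
is treated as the truth: its ``g`` genes are all the genes there are, and
its empirical frequencies ``y_i / N`` are maximum-likelihood estimates of
the expression probabilities.  Subsampling it at a smaller depth ``N_i``
then yields pairs ``(f0_hat_i, f0_i)`` in which the true number of missing
genes ``f0_i = g - g_i`` is known, so competing estimators can be scored by
their estimated standard error

    se(f0_hat) = sqrt( (1/B) * sum_i (f0_hat_i - f0_i)^2 )

over ``B`` replicates with depths drawn uniformly from a working range.
The same machinery, applied to an *incomplete* sample resampled at its own
depth, gives an approximate standard error and normal 95% confidence
interval for the sample's own f0_hat.

Randomness contract: one master seed; replicate ``i`` uses a generator
seeded from ``(seed, i)`` via ``numpy.random.SeedSequence``, so results are
reproducible regardless of execution order or parallel scheduling.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from itertools import combinations
from typing import Callable, Mapping, Sequence

import numpy as np

from .spectrum_io import (
    CountVector,
    FrequencySpectrum,
    RichnessEstimate,
    is_complete,
    spectrum_from_array,
    spectrum_from_counts,
)

__all__ = [
    "BootstrapConfig",
    "EvaluationResult",
    "replicate_rng",
    "bootstrap_sample",
    "estimate_se_bias_ci",
    "run_selection_harness",
    "prob_all_detected",
]

Z_95 = 1.96  # normal quantile used for the approximate 95% interval


@dataclass(frozen=True)
class BootstrapConfig:
    """Knobs of the bootstrap procedures.

    ``B``
        replicates.  1000 by default for per-sample SE/CI work; the
        selection harness benefits from more when time allows.
    ``distribution``
        ``"multinomial"`` (fixed replicate total, equivalent to the
        non-parametric bootstrap) or ``"poisson"`` (independent per-gene
        counts with the same expectations).
    ``n_min``, ``n_max``
        uniform range of replicate depths for the selection harness, in
        tags.  Defaults to one million as the floor below which estimator
        behaviour is erratic; ``n_max=None`` means the reference depth.
    ``drop_degenerate``
        drop replicates where an estimator was undefined (default) instead
        of zero-filling them; either way the count is reported.
    ``ci_method``
        ``"normal"`` (f0_hat +/- 1.96 se, clamped at 0) or ``"percentile"``.
    """

    B: int = 1000
    distribution: str = "multinomial"
    n_min: int = 1_000_000
    n_max: int | None = None
    seed: int = 0
    drop_degenerate: bool = True
    ci_method: str = "normal"

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if self.distribution not in ("multinomial", "poisson"):
            raise ValueError("distribution must be 'multinomial' or 'poisson'")
        if self.n_min < 1:
            raise ValueError("n_min must be >= 1")
        if self.n_max is not None and self.n_max < self.n_min:
            raise ValueError("need n_min <= n_max")
        if self.ci_method not in ("normal", "percentile"):
            raise ValueError("ci_method must be 'normal' or 'percentile'")
        if self.seed < 0:
            raise ValueError("seed must be >= 0")


@dataclass(frozen=True)
class EvaluationResult:
    """Score card of one estimator over the selection harness replicates."""

    estimator_name: str
    se: float
    r_squared: float
    error_min: float
    error_median: float
    error_mean: float
    error_max: float
    n_degenerate: int
    n_used: int


def replicate_rng(seed: int, index: int) -> np.random.Generator:
    """Deterministic per-replicate generator derived from (seed, index)."""
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(int(index),)))


def bootstrap_sample(
    reference: CountVector,
    N_i: int,
    distribution: str = "multinomial",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[FrequencySpectrum, int]:
    """One parametric bootstrap draw from a reference sample's empirical
    distribution, returning the replicate spectrum and its true ``f0``.

    The reference's ``g`` genes play the role of the truth ``G``; the draw
    is multinomial(``N_i``, ``y/N``) (total exactly ``N_i``) or independent
    Poisson with rates ``N_i * y_i / N`` (total random with expectation
    ``N_i``).  ``true_f0`` is the number of reference genes absent from the
    draw.
    """
    N_i = int(N_i)
    if N_i < 1:
        raise ValueError("replicate depth N_i must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    p = reference.counts / reference.N
    if distribution == "multinomial":
        draw = rng.multinomial(N_i, p)
    elif distribution == "poisson":
        draw = rng.poisson(N_i * p)
    else:
        raise ValueError("distribution must be 'multinomial' or 'poisson'")
    positive = draw[draw > 0]
    return spectrum_from_array(positive), reference.g - int(positive.size)


def normal_ci(f0_hat: float, se: float) -> tuple[float, float]:
    """Approximate 95% interval ``f0_hat +/- 1.96 se``, lower bound clamped at 0."""
    return max(f0_hat - Z_95 * se, 0.0), f0_hat + Z_95 * se


def estimate_se_bias_ci(
    sample: CountVector,
    estimator: Callable[[FrequencySpectrum], RichnessEstimate],
    config: BootstrapConfig = BootstrapConfig(),
) -> RichnessEstimate:
    """Point estimate plus bootstrap SE and 95% CI for one sample.

    ``B`` replicates are drawn at the sample's own depth from its empirical
    distribution; in each, the replicate truth ``f0_i = g - g_i`` is known
    because the observed sample plays the role of the complete population.
    The SE is the root mean squared error of the estimator over replicates;
    the default CI is the normal approximation clamped at zero, with a
    percentile bootstrap available via ``config.ci_method``.

    Degenerate replicates are dropped (or zero-filled) per
    ``config.drop_degenerate``; if every replicate is degenerate a
    ``RuntimeError`` is raised.
    """
    if sample.g == 0:
        raise ValueError("sample has no detected genes")
    point = estimator(spectrum_from_counts(sample))
    errors: list[float] = []
    estimates: list[float] = []
    n_degenerate = 0
    for i in range(config.B):
        rng = replicate_rng(config.seed, i)
        rep_spec, f0_i = bootstrap_sample(sample, sample.N, config.distribution, rng=rng)
        est_i = estimator(rep_spec)
        value = est_i.f0_hat
        if math.isnan(value):
            n_degenerate += 1
            if config.drop_degenerate:
                continue
            value = 0.0
        errors.append(value - f0_i)
        estimates.append(value)
    if not errors:
        raise RuntimeError("all bootstrap replicates were degenerate for this estimator")
    err = np.asarray(errors)
    se = float(np.sqrt(np.mean(err**2)))
    if config.ci_method == "normal":
        lo, hi = normal_ci(point.f0_hat, se)
    else:
        lo, hi = (float(q) for q in np.quantile(np.asarray(estimates), [0.025, 0.975]))
        lo = max(lo, 0.0)
    if math.isnan(point.f0_hat):
        lo = hi = math.nan
    return replace(point, se=se, ci_lower=lo, ci_upper=hi)


def run_selection_harness(
    complete: CountVector,
    estimators: Mapping[str, Callable[[FrequencySpectrum], RichnessEstimate]],
    config: BootstrapConfig = BootstrapConfig(),
) -> dict[str, EvaluationResult]:
    """Score candidate estimators against known truth by subsampling a
    complete reference.

    For each replicate a depth ``N_i`` is drawn uniformly on
    ``[n_min, n_max]``, a bootstrap sample is taken, and every estimator is
    evaluated on its spectrum; the replicate truth is ``f0_i = g - g_i``.
    Returns one :class:`EvaluationResult` per estimator with the bootstrap
    standard error, the squared Pearson correlation between estimates and
    truths, and the error quantiles.
    """
    spec0 = spectrum_from_counts(complete)
    if not is_complete(spec0):
        warnings.warn(
            f"reference sample is not complete (f1 = {spec0[1]}); "
            "replicate truths treat its g genes as all there are",
            stacklevel=2,
        )
    n_max = complete.N if config.n_max is None else config.n_max
    if config.n_min > complete.N:
        raise ValueError(f"n_min = {config.n_min} exceeds the reference depth N = {complete.N}")
    if n_max > complete.N:
        raise ValueError(f"n_max = {n_max} exceeds the reference depth N = {complete.N}")
    names = list(estimators)
    fhat: dict[str, list[float]] = {k: [] for k in names}
    truth: dict[str, list[float]] = {k: [] for k in names}
    n_degenerate = dict.fromkeys(names, 0)
    for i in range(config.B):
        rng = replicate_rng(config.seed, i)
        N_i = int(rng.integers(config.n_min, n_max + 1))
        rep_spec, f0_i = bootstrap_sample(complete, N_i, config.distribution, rng=rng)
        for name in names:
            value = estimators[name](rep_spec).f0_hat
            if math.isnan(value):
                n_degenerate[name] += 1
                if config.drop_degenerate:
                    continue
                value = 0.0
            fhat[name].append(value)
            truth[name].append(float(f0_i))
    results: dict[str, EvaluationResult] = {}
    for name in names:
        est = np.asarray(fhat[name])
        tru = np.asarray(truth[name])
        if est.size == 0:
            raise RuntimeError(f"all replicates were degenerate for estimator {name!r}")
        err = est - tru
        if est.size >= 2 and est.std() > 0 and tru.std() > 0:
            r2 = float(np.corrcoef(est, tru)[0, 1] ** 2)
        else:
            r2 = 0.0  # a constant estimator explains none of the variance
        results[name] = EvaluationResult(
            estimator_name=name,
            se=float(np.sqrt(np.mean(err**2))),
            r_squared=r2,
            error_min=float(err.min()),
            error_median=float(np.median(err)),
            error_mean=float(err.mean()),
            error_max=float(err.max()),
            n_degenerate=n_degenerate[name],
            n_used=int(est.size),
        )
    return results


def _probability_vector(population) -> np.ndarray:
    p = np.asarray(getattr(population, "p", population), dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ValueError("probability vector must be 1-D and non-empty")
    if (p <= 0).any():
        raise ValueError("all probabilities must be > 0")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("probabilities must sum to 1")
    return p


def prob_all_detected(population, N: int, method: str = "approx") -> float:
    """Probability that a sample of ``N`` tags detects every gene.

    ``method="approx"`` multiplies the per-gene marginal detection
    probabilities, ``prod_i (1 - (1 - p_i)^N)``, ignoring the (negative)
    multinomial dependence between genes; the approximation overstates the
    probability at very small ``N`` and tightens quickly as ``N`` grows.
    ``method="exact"`` evaluates the inclusion-exclusion sum
    ``sum_S (-1)^|S| (1 - p(S))^N`` and is available for up to 12 genes as
    an oracle.  ``population`` may be a probability vector or anything with
    a ``.p`` attribute.
    """
    p = _probability_vector(population)
    N = int(N)
    if N < 0:
        raise ValueError("N must be >= 0")
    if N == 0:
        return 0.0 if p.size >= 1 else 1.0
    if method == "approx":
        with np.errstate(divide="ignore", invalid="ignore"):
            # 1 - (1-p)^N computed in log space for depth stability
            terms = -np.expm1(N * np.log1p(-np.minimum(p, 1.0)))
        return float(np.exp(np.sum(np.log(terms))) if (terms > 0).all() else 0.0)
    if method == "exact":
        G = p.size
        if G > 12:
            raise ValueError("exact inclusion-exclusion is limited to G <= 12")
        total = 0.0
        for k in range(G + 1):
            for subset in combinations(range(G), k):
                miss = p[list(subset)].sum()
                total += (-1) ** k * (1.0 - miss) ** N
        return float(min(max(total, 0.0), 1.0))
    raise ValueError("method must be 'approx' or 'exact'")
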