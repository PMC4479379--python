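"""Known-truth transcriptome populations and samplers.

Real transcriptomes are heavy-tailed: a few transcripts dominate the tag
pool while most genes are rare.  The generator draws relative abundances
from a log-normal or Pareto law (or uniform, for degenerate checks),
normalises them into a probability vector of length ``G``, and samples tags
with replacement — multinomially at a fixed depth, or with independent
Poisson counts of the same expectations.  Because ``G`` is chosen, the true
number of missing genes in any sample is known exactly, which is what the
estimator-selection harness and all validation tests rely on.

The default scenario used across tests and documentation is ``G = 5000``
genes with log-normal(meanlog=0, sdlog=1.5) abundances; sdlog=1.5 spans
roughly four orders of magnitude of expression, typical of bulk RNA-seq,
while keeping ``f2..f6`` positive (hence h6 non-degenerate) at working
depths.  What the generator deliberately omits: read-level artifacts such
as mapping error, multimapping and library-preparation bias — its samples
are ideal draws from the with-replacement model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .spectrum_io import CountVector

__all__ = [
    "SyntheticPopulation",
    "make_population",
    "draw_sample",
    "make_complete_reference",
    "default_population",
    "default_complete_reference",
    "DEFAULT_G",
    "DEFAULT_MODEL_PARAMS",
]

DEFAULT_G = 5000
DEFAULT_MODEL_PARAMS: Mapping[str, float] = {"meanlog": 0.0, "sdlog": 1.5}


@dataclass(frozen=True)
class SyntheticPopulation:
    """A complete transcriptome with known truth: ``G`` genes and their
    relative expression probabilities ``p`` (positive, summing to 1)."""

    p: np.ndarray
    model: str
    params: Mapping[str, float]
    seed: int | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "p", p)
        object.__setattr__(self, "params", dict(self.params))
        if p.ndim != 1 or p.size < 1:
            raise ValueError("p must be a non-empty 1-D vector")
        if (p <= 0).any():
            raise ValueError("all p_i must be > 0")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("p must sum to 1")

    @property
    def G(self) -> int:
        return int(self.p.size)

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(f"gene{i:05d}" for i in range(self.G))


def make_population(
    G: int,
    model: str = "lognormal",
    params: Mapping[str, float] | None = None,
    seed: int | None = None,
) -> SyntheticPopulation:
    """Draw a population of ``G`` genes from an abundance model.

    Models and their parameters:

    * ``lognormal``: ``meanlog`` (default 0), ``sdlog`` (default 1.5, > 0);
    * ``pareto``: ``alpha`` (tail index, default 1.2, > 0), ``xmin``
      (default 1, > 0) — heavier-tailed than any log-normal;
    * ``uniform``: all genes equally expressed (no parameters);
    * ``from_counts``: ``counts`` (positive integers) — turns an observed
      count vector into the truth via ``p_i = y_i / N``.

    Deterministic under ``seed``; weights are normalised after the draw.
    """
    G = int(G)
    if G < 1:
        raise ValueError("G must be >= 1")
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if model == "lognormal":
        meanlog = float(params.pop("meanlog", 0.0))
        sdlog = float(params.pop("sdlog", 1.5))
        if sdlog < 0:
            raise ValueError("sdlog must be >= 0")
        weights = rng.lognormal(meanlog, sdlog, size=G)
        used = {"meanlog": meanlog, "sdlog": sdlog}
    elif model == "pareto":
        alpha = float(params.pop("alpha", 1.2))
        xmin = float(params.pop("xmin", 1.0))
        if alpha <= 0 or xmin <= 0:
            raise ValueError("alpha and xmin must be > 0")
        weights = xmin * (1.0 + rng.pareto(alpha, size=G))
        used = {"alpha": alpha, "xmin": xmin}
    elif model == "uniform":
        weights = np.ones(G)
        used = {}
    elif model == "from_counts":
        counts = np.asarray(params.pop("counts"), dtype=float)
        if counts.size != G:
            raise ValueError("from_counts needs len(counts) == G")
        if (counts <= 0).any():
            raise ValueError("from_counts needs strictly positive counts")
        weights = counts
        used = {}
    else:
        raise ValueError(f"unknown abundance model {model!r}")
    if params:
        raise ValueError(f"unknown parameters for model {model!r}: {sorted(params)}")
    return SyntheticPopulation(weights / weights.sum(), model, used, seed)


def draw_sample(
    pop: SyntheticPopulation,
    N: int,
    distribution: str = "multinomial",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[CountVector, int]:
    """Sample ``N`` tags with replacement from the population.

    Returns the detected genes as a :class:`CountVector` (zero-count genes
    are dropped) together with the true number of missing genes
    ``f0 = G - g``.  Multinomial draws total exactly ``N``; Poisson draws
    use independent counts with rates ``N * p_i``.
    """
    N = int(N)
    if N < 1:
        raise ValueError("N must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    if distribution == "multinomial":
        draw = rng.multinomial(N, pop.p)
    elif distribution == "poisson":
        draw = rng.poisson(N * pop.p)
    else:
        raise ValueError("distribution must be 'multinomial' or 'poisson'")
    keep = draw > 0
    ids = tuple(f"gene{i:05d}" for i in np.flatnonzero(keep))
    cv = CountVector(ids, draw[keep])
    return cv, pop.G - cv.g


def make_complete_reference(
    pop: SyntheticPopulation,
    target_N: int = 2_000_000,
    seed: int | None = 0,
    distribution: str = "multinomial",
    max_doublings: int = 14,
) -> CountVector:
    """Draw a complete sample (``f1 = 0`` and ``g = G``) for harness use.

    Starts at ``target_N`` tags and doubles the depth until the draw is
    complete, up to ``max_doublings``; for heavy-tailed populations the
    complete depth is governed by the rarest gene and typically lands one
    to two orders of magnitude above the starting point.  Raises with the
    achieved ``f1`` if the cap is reached first.
    """
    last_f1 = None
    base = 0 if seed is None else int(seed)
    for attempt in range(max_doublings + 1):
        N = int(target_N) << attempt
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=base, spawn_key=(attempt,))
        )
        cv, f0 = draw_sample(pop, N, distribution, rng=rng)
        singletons = int((cv.counts == 1).sum())
        if singletons == 0 and f0 == 0:
            return cv
        last_f1 = singletons
    raise RuntimeError(
        f"no complete sample within {max_doublings} doublings of N = {target_N}; "
        f"last attempt had f1 = {last_f1}"
    )


def default_population(seed: int = 0) -> SyntheticPopulation:
    """The package's reference scenario: G=5000, log-normal(0, 1.5)."""
    return make_population(DEFAULT_G, "lognormal", DEFAULT_MODEL_PARAMS, seed=seed)


def default_complete_reference(seed: int = 0) -> CountVector:
    """Complete reference sample from the default scenario (doubling from 2e6 tags)."""
    return make_complete_reference(default_population(seed), target_N=2_000_000, seed=seed)
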