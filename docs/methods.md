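# Methods

## Sampling model

A sequencing library is modelled as *N* independent draws (gene tags) with
replacement from an effectively infinite transcript pool with relative
expression probabilities *p₁ … p_G*, *G* unknown.  The per-gene counts are
multinomial(*N*, *p*); Poissonization (independent counts with means
*N·pᵢ*) is offered everywhere as the alternative and differs negligibly at
RNA-seq depths.  All estimators depend on the data only through the
frequency-of-frequencies spectrum *f_r*, which is sufficient here: any two
samples with the same spectrum get identical estimates, so everything is
invariant to gene labels and permutations (property-tested).

Because *G* is unknown the parameter space is open and maximum likelihood
does not apply; and because the abundance law varies wildly across tissues
and protocols, we avoid parametric richness models (log-normal or
Pareto mixtures) entirely and stay nonparametric.  The estimand is *f₀*,
the number of expressed genes with zero tags; *G = g + f₀*.

## Estimators and degenerate cases

Closed forms are listed in the README.  Numerical conventions:

* Estimates are floats throughout; rounding to integers happens only in
  reports (`digits=0`, the convention of published survey tables).
* A complete sample, defined operationally as *f₁ = 0*, forces every
  estimator to exactly 0.  This is also the reference criterion used to
  treat a deeply sequenced sample as the truth.
* None of the raw estimators has a finite expectation, because their
  denominators are zero with positive probability.  Handling:
  * Chao1 with *f₂ = 0, f₁ > 0* falls back to the bias-corrected Chao2
    form (standard practice in ecological software), flagged
    `degenerate=True`.
  * The Pythagorean family (including h6) returns NaN with
    `degenerate=True` when a required *f_r* is 0 — no standard correction
    exists and silently substituting one would bias bootstrap summaries.
    Downstream code drops and counts such replicates (zero-filling is
    selectable).
  * iChao1: a zero *f₂* makes its base term fall back as in Chao1; a zero
    *f₄* with *f₃ > 0* drops the correction term, reverting to the Chao1
    lower bound; both flag the estimate.
* h6's constant is the literal rational 6/10; h6 is implemented as the
  harmonic family member of degree 6 so the two entry points are
  bit-identical.
* The Medial estimator defaults to its approximate form; the exact
  (N−1)/N factor matters only at depths far below RNA-seq practice.
* Good's coverage is 1 − f₁/N; the Good–Turing adjusted count
  r* = (r+1)f_{r+1}/f_r raises an error when f_r = 0 rather than guessing.

## Bootstrap standard errors and intervals

`estimate_se_bias_ci` resamples the observed sample at its own depth; the
sample's *g* plays the role of *G*, so each replicate's truth
*f₀ᵢ = g − gᵢ* is known and se(f̂₀) = √(B⁻¹ Σ(f̂₀ᵢ − f₀ᵢ)²).  The default
interval is the normal approximation f̂₀ ± 1.96·se with the lower bound
clamped at zero — with integer rounding this reproduces the convention of
published per-accession tables (e.g. 1613 ± 1.96·52 → [1511, 1715]).  A
percentile bootstrap is available for skewed cases.  Default B = 1000 for
per-sample work; the selection studies below use what their runtime allows.

Randomness contract: replicate *i* draws from a generator seeded by
`SeedSequence(entropy=seed, spawn_key=(i,))`.  Results are bit-reproducible
for a given seed and independent of evaluation order; every CLI command
repeated with the same seed writes a byte-identical report (tested).

## Estimator selection harness

`run_selection_harness` subsamples a complete reference at depths uniform
on [n_min, n_max] and scores each candidate by se, by the squared Pearson
correlation between estimates and truths, and by error quantiles.  The
floor n_min defaults to one million tags for real accessions, below which
the estimators' behaviour is erratic; synthetic studies scale it as a
fraction of the reference depth instead.  Degenerate replicates are
dropped per estimator and counted (the alternative, zero-filling, is a
config switch; dropping is the default because a zero fill would reward an
estimator for refusing to answer exactly where it is weakest).

## Synthetic known-truth transcriptomes

The generator draws abundances from log-normal (default), Pareto, or
uniform laws, normalises to probabilities, and samples multinomially or
by Poisson.  The default scenario is G = 5000 genes, log-normal(meanlog 0,
sdlog 1.5) — about four decades of expression — with the complete
reference built by doubling the depth from 2×10⁶ tags until *f₁ = 0* and
*g = G* hold simultaneously.  The complete depth is governed by the rarest
gene and typically lands at 1–6×10⁷ tags (16×10⁶ for the suite's seed);
because multinomial sampling costs O(G) regardless of depth, this has no
runtime consequence.  A `from_counts` model turns any observed count
vector into a truth via *pᵢ = yᵢ/N*, mirroring how a real complete
accession is used as a reference.

At these study sizes (B = 2000 replicates, depths 1%–100% of the complete
depth) the suite reproduces the directional selection result: se(h6) <
se(Medial) < se(Chao1), r²(h6) ≥ r²(Chao1), and h6's median error within
5% of G.  What passing these tests does *not* show: the generator omits
mapping error, multimapping, library-preparation bias and gene-definition
ambiguity, and the log-normal tail is milder than some real accessions —
absolute error magnitudes on real data can be larger than the synthetic
ones, which is why the per-sample bootstrap SE, not the synthetic study,
is the error bar to quote.

`prob_all_detected` gives the probability that a depth-*N* sample detects
every gene: a product of per-gene marginals (fast, any *G*) or an exact
inclusion–exclusion sum (*G* ≤ 12, used as an oracle).  The product form
ignores the negative dependence between genes and overstates the
probability at very small *N* (e.g. 0.52 vs 0.44 exact for three uniform
genes at *N* = 4); the gap is below 0.02 by *N* = 6 and negligible at
realistic depths.

## Extra sample size

Both closed forms (README) assume the undiscovered genes are rare and
their discovery rate decays exponentially with additional depth; they are
subject to the positivity condition f̂₀/(Ĝ(1−ψ)) > 1, return 0 exactly on
complete samples, and diverge as ψ → 1.  The logarithm is natural.  When
the condition fails, the CLI reports that the target proportion is already
within reach of the current depth rather than inventing a number.

Methods are compared by the weighted squared error
WSE = ((g + ψf̂₀ − E[G | N+m]) / f̂₀)², the squared gap between the
promised and expected detected-gene totals in units of the estimated
deficit.  E[G | N+m] = Σᵢ (1 − e^{−(N+m)pᵢ}) by Poissonization when the
truth is known, by bootstrap averaging otherwise.  Two design choices:

* **Probe depths.**  The comparison defaults to depths of 0.1%–2% of the
  reference, chosen from the missing-fraction profile so that replicates
  miss roughly 3%–40% of genes — the regime where depth planning is live.
  At near-complete depths the positivity condition fails by construction
  and replicates are only counted.
* **Paired summaries.**  The condition fails on different replicates for
  different methods (a low-biased f̂₀ gives up earliest, precisely where
  its own WSE is flattering), so mean WSE is reported over the replicates
  where *every* method answered.  Unpaired per-method summaries remain
  available (`paired=False`).

Under the default scenario the h6-style formula's paired mean WSE is
~40% below the Chao-style one, stable across seeds.  An oracle method
that numerically inverts the expected-detection curve (Brent's method on
the Poissonized curve) achieves WSE ≈ 0 and anchors the harness.

Known limitation: on the default synthetic population at very shallow
depths the h6-style plan under-delivers — actually drawing the planned
extra tags recovers ~55–70% of the promised ψ·f̂₀ gain (the empirical
validation test encodes a factor-two accuracy band).  Near the positivity
boundary both formulas under-plan severely (m → 0 while the promised gain
stays finite); treat plans with f̂₀/(Ĝ(1−ψ)) barely above 1 as lower
bounds on the needed depth.

## Input handling

Count tables are delimited text, gene id first, one column per library,
mandatory header; the delimiter follows the extension (.csv/.tsv) unless
overridden.  Raw integer counts are required — normalised values (TPM/CPM)
destroy the sampling model and are rejected with the offending line
number.  Zero rows are kept in the matrix (a gene absent in one library
may appear in another) but never in a per-sample count vector, where
"detected" means at least one tag.  Gene identity is the row identifier
verbatim: the package imposes no splice-variant or paralog grouping, so
estimates are always relative to the study's own definition of "gene".
Spectra are stored sparsely with no upper bound on r.
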