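# generich

**How many expressed genes did your RNA-seq sample miss?**

An RNA-seq experiment samples gene tags with replacement from the transcript
pool: weakly expressed genes can easily end up with zero tags and look
"not expressed" when they are merely undetected.  `generich` estimates the
number of missing genes *f₀* from nothing but the sample's
frequency-of-frequencies spectrum, attaches bootstrap standard errors and
confidence intervals, and computes the extra sequencing depth needed to
observe a chosen proportion of the missing genes.  It is aimed at anyone
deciding whether a library has been sequenced deeply enough — or whether an
absent gene can honestly be called "not expressed".

## The statistics in brief

Let *yᵢ* be the tag count of detected gene *i*, *N* = Σ *yᵢ* the depth,
*g* the number of detected genes, and *f_r* = #{*i* : *yᵢ* = *r*} the
frequency of frequencies (*f₁* singletons, *f₂* doubletons, …).  The true
number of expressed genes is *G* = *g* + *f₀*, with *f₀* unobserved.
Estimators provided:

| name | formula |
|---|---|
| Chao1 | *f₁² / (2 f₂)* |
| Chao2 (bias-corrected) | *f₁(f₁−1) / (2(f₂+1))* |
| iChao1 | Chao1 + *(f₃/4f₄)·max(f₁ − f₂f₃/2f₄, 0)* |
| Medial | *f₁(f₁−1)/(f₂+1)* (optionally × (N−1)/N) |
| **h6** | *(6/10)·f₁² / H(f₂,…,f₆)*, *H* the harmonic mean |
| Pythagorean family | *u·f₁² / c(f₂,…,f_degree)*, *c* ∈ {arithmetic, geometric, harmonic} |

RNA-seq depths are large enough that *f₃…f₆* are informative, which
ecology-scale samples cannot exploit; **h6** — the harmonic-mean member of
the family — is the estimator selected by parametric-bootstrap evaluation
against known-truth subsamples of a complete reference (a sample with
*f₁ = 0*), and is the package default.  Standard errors use
se(f̂₀) = √(B⁻¹ Σ (f̂₀ᵢ − f₀ᵢ)²) over bootstrap replicates with known
replicate truth, with 95% intervals f̂₀ ± 1.96·se clamped at zero.

The extra depth needed to detect a proportion ψ of the missing genes
(Ĝ = g + f̂₀, natural log, valid when f̂₀/(Ĝ(1−ψ)) > 1):

* Chao-style  m = N·(f₁/2f₂)·ln[f̂₀/(Ĝ(1−ψ))]
* h6-style   m′ = N·(h₆/f₁)·ln[h₆/(Ĝ(1−ψ))]

## Worked example

Simulate a known-truth transcriptome of G = 5000 genes with log-normal
abundances, sampled shallowly (100 000 tags), then estimate what was missed:

```bash
$ generich simulate --G 5000 --N 100000 --seed 7 --out shallow.tsv
# wrote shallow.tsv: G=5000 g=4520 N=100000 true_f0=480

$ generich estimate shallow.tsv --estimator h6,chao1,medial --bootstrap 500 --seed 42
sample          N       g     f0_hat  se   ci_lower  ci_upper  pct_missing  estimator
shallow:total   100000  4520  491     77   340       642       10           h6
shallow:total   100000  4520  290     68   157       423       6            chao1
shallow:total   100000  4520  578     146  291       864       11           medial
```

The sample truly missed 480 genes.  h6 answers 491 with a 95% interval
[340, 642] that covers the truth; Chao1, a lower bound, underestimates at
290.  About 10% of the expressed genes are invisible at this depth.  How
much more sequencing would recover 95% of them?

```bash
$ generich extrasample shallow.tsv --psi 0.95 --method both
h6    psi=0.95  f0_hat=491.2  m_extra=67085
chao  psi=0.95  f0_hat=290.0  m_extra=11017
```

The h6-style plan asks for ~67 000 extra tags; the Chao-style plan, built
on the underestimated f̂₀, asks for far fewer than it should.  When a
sample is complete (*f₁ = 0*) every estimator returns 0 and the required
extra depth is 0; conversely ψ → 1 diverges — no finite depth guarantees
nothing is missing.

The same machinery works on real count tables (genes × libraries, raw
integer counts, e.g. GEO/ArrayExpress supplementary files): `--library X`
analyses one column, the default collapses all libraries into the
accession's total library.  A bare spectrum (`r`, `f_r` per line) can be
analysed with `--spectrum`.  `generich evaluate` scores estimators against
a complete reference; library functions expose everything programmatically
(`generich.h6`, `generich.run_selection_harness`, …).

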