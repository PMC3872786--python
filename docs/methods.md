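# Methods

## Co-occurrence space

The space is a sparse word-by-dimension matrix in the HAL family. A window
of `window_behind` positions before and `window_ahead` after each target
token (defaults 5/5) is scanned; a context hit at distance *d* contributes
weight *w(d)* to the cell (target, context). Three weighting schemes are
implemented — `inverse_ramp` *w(d)* = 1/*d* (default), `ramp`
*w(d)* = L−*d*+1, and `flat` *w(d)* = 1. "Inverse ramp" is implemented as
1/*d*: the originating co-occurrence toolchain does not publish the exact
formula, so the scheme is an enum and alternatives are testable. Windows
cross sentence boundaries but never document boundaries (the corpus reader
treats one line, or one file, as a document). Behind and ahead
contributions are summed into a single vector per word by default; a
`concatenate_windows` flag keeps them as separate column blocks for users
who want direction-sensitive vectors.

Columns ("dimension words") are the `context_size` most frequent
vocabulary items (default 10,000), with frequency ties broken
lexicographically so space construction is fully deterministic. Words
below `min_word_count` are excluded from the vocabulary altogether, with a
logged count.

**PPMI.** Each weighted count becomes
max(0, ln(p(w,c) / (p(w)·p(c)))) with probabilities from the
weighted-count marginals. The log base is natural; base only rescales
vectors and cosine similarity is scale-invariant, so this is a
reproducibility pin, not a modeling choice. PPMI is invariant to
duplicating the corpus and to document order, and the matrix is
non-negative — all property-tested.

**Similarity** is cosine throughout; for non-negative PPMI vectors it lies
in [0, 1]. Zero vectors have undefined similarity and raise (single-word
API) or propagate NaN with a warning (bulk API); downstream tables drop
such rows with a logged count rather than zero-filling.

## Neighborhood density

The neighborhood membership threshold is θ = μ + λσ, where μ and σ are the
mean and SD of cosine similarity over randomly sampled distinct word pairs
(default 1,000,000 pairs, capped at the number of distinct pairs, always
seeded; when the cap binds, all distinct pairs are enumerated exactly
once). λ defaults to 1.5 and is a required, logged parameter of every
neighborhood table: the upstream toolchain's exact threshold function is
not published, so λ is exposed for calibration rather than guessed at.

For a word *w*: neighbors are vocabulary items (never *w* itself) with
cos ≥ θ; NCOUNT is their number; INV-NCOUNT = 1/(NCOUNT+1) ∈ (0,1];
ARC is the mean similarity to the neighbors, computed on similarities
(not distances) so that denser/tighter neighborhoods give larger ARC.
An empty neighborhood has undefined ARC, emitted as missing — regressions
drop such rows with a logged count, because imputing 0 would conflate
"no neighbors" with "maximally distant neighbors".

## Predictors and norms

Emotion-term features are cosine similarities to seed terms from a 78-term
pool of proposed "basic emotion" vocabulary, shipped as a versioned JSON
resource together with the 8-term and 7-term subsets used by the published
models. The resource's `variant_forms` set is a reconstruction: it holds
adjectival/derived surface forms of the theorists' terms (including the
four forms that appear in the published models) because the full published
enumeration of surface forms is not available in machine-readable form;
the set is labelled as such in the resource.

Lexical covariates: LENGTH in letters; LNFREQUENCY = ln(raw corpus count)
with zero-count words excluded rather than smoothed (a per-million rate
can be supplied by using an external frequency table); ON is Coltheart's
orthographic neighborhood — same-length words differing in exactly one
substitution — the standard operationalization where only the name of the
measure is fixed.

Rating norms from multiple sources are merged by affinely mapping each
source's declared [lo, hi] scale onto [1, 7] and averaging (unweighted)
per word; the merge is invariant to source order and validates every
rating against its declared bounds.

## Regression machinery

`fit_ols` wraps a standard OLS fit (statsmodels) and exposes coefficients,
classical SEs, two-sided t tests, r², and AIC. The AIC convention is the
Gaussian log-likelihood including its 2π constant; only AIC differences
between models of the same data are meaningful, and the convention is
pinned so reported differences are reproducible. Rank-deficient designs
raise an error naming the collinear columns (found by incremental rank
growth), rather than silently dropping them.

Backwards elimination refits OLS and removes the predictor with the
largest p-value (equivalently smallest |t|) until `k` remain — the
standard reading of removing the term that "predicts least well". P-value
ties are broken by predictor name so the removal sequence is invariant to
column order; the full elimination trace is recorded in the model's
provenance. Split-half validation partitions the norm table uniformly at
random (sizes differ by ≤ 1) under a seed.

The three published coefficient tables ship as JSON resources and are
applied unclamped: the linear score is the quantity of interest, and the
published summary statistics (mean computed judgment 4.3, z-scored
variants) imply no clamping; out-of-range predictions are counted and
logged. Composite CONTEXT and EMOTIONALITY scores are the β-weighted
density and emotion-term parts of the full model, z-scored over the scored
set (z-scoring a single row, or a zero-spread column, is an error, not a
silent NaN).

The random-word control samples disjoint sets of medium-frequency words
(default 10–500 occurrences per million, excluding the emotion terms and
all normed words), builds similarity features to each set, backwards-
eliminates to `k` on the test half, and reports test/validation
correlations per set plus the pooled correlation between selected βs and
each word's sign-weighted summed similarity to the emotion terms (the
"valence proxy").

## RT analyses

Trial preprocessing applies, in a pinned order: (1) subject exclusion at
accuracy more than 2.5 SDs below the across-subject mean; (2) removal of
error and non-word trials; (3) absolute fast cut (< 400 ms); (4) absolute
slow cut (> 4000 ms); (5) z-trim at 2.5 SDs of the remaining distribution.
Each step's statistics are computed on what the previous steps left, so
the order is part of the contract and is tested. The z-trim is two-sided
by default (the spec of the step is "beyond 2.5 SDs"); a `two_sided_z`
flag recovers slow-tail-only trimming. By-item aggregation is the mean
correct-word RT per item.

Variance partitioning regresses by-item RT on the lexical covariates
(ON, LENGTH, LNFREQUENCY), then measures the r² of imageability on those
residuals ("before"), and again on the residuals of the model additionally
containing CONTEXT, EMOTIONALITY and their interaction ("after"); the
interaction is included because it is reliably present in this kind of
data. Mixed-effects fitting is deliberately out of scope; the surrogate
is by-item fixed-effects OLS with AIC comparison.

±1z categorization is strict (> 1z high, < −1z low, boundary values mid;
"low" is z < −1, since a literal `< 1z` cut would overlap mid). The
category grid reports, per 3×3 cell, the count, within-group proportion,
covariate-adjusted mean RT (residuals plus grand mean, keeping
milliseconds; any alternative adjusted-at-covariate-means convention
differs only by a constant that cancels in every difference reported) and
SE = sd/√n. Empty cells keep count 0 and missing RTs — never fabricated
values. The proportional-sampling null effect is Σp_low·m − Σp_high·m over
shared cell means m, positive when the low group is expected slower.

The reliability-ceiling arithmetic converts a correlation r₁ observed at
n₁ to the equivalent correlation at n₂ by equating t statistics
(t = r√(n−2)/√(1−r²); r₂ = t/√(n₂−2+t²)), and expresses a model's
explained variance as a percentage of that ceiling.

## Synthetic data

The generators emulate exactly the stages the analyses consume:

- **Corpus**: a topic mixture. The vocabulary is split evenly over
  `n_topics` topics; each document draws a topic and samples tokens from
  it, with probability `mixing` of drawing from the whole vocabulary
  instead. Same-topic words provably co-occur more than cross-topic words
  (with `mixing = 0`, cross-topic co-occurrence is exactly zero), which is
  the feature under test — no attempt is made at realistic syntax, and
  word probabilities are uniform unless a power-law tilt (`zipf_s`) is
  requested. Note that with little mixing the similarity structure is
  near-block-constant: every word in a topic gets the same NCOUNT, and
  cross-topic similarity columns can be exactly zero. Tests that need
  well-conditioned similarity features use heavier mixing (0.3).
- **Ratings**: y = β₀ + Σβᵢxᵢ + N(0, σ) over computed features, with the
  generating coefficients returned as ground truth. Defaults (intercept 4,
  σ = 0.5 on the 1–7 scale) put the signal-to-noise in the range where a
  few hundred items identify moderate coefficients.
- **Trials**: rt = baseline + Σeffectᵢxᵢ + subject intercept + N(0, σ),
  with defaults (baseline 650 ms, subject SD 40 ms, residual SD 60 ms,
  ~30 subjects, 3–5% error rate) matching typical visual lexical decision
  magnitudes; planted outliers are drawn far outside the 400–4000 ms
  window so the absolute filters must recover exactly the planted count.

Generators are pure functions of their spec (same seed ⇒ identical
output) and ground truth travels beside the data, never through the
analysis path. Passing tests on these generators shows the machinery is
correct and well-calibrated at desk scale; it does not show that a small
synthetic corpus reproduces the numerical coefficient values obtained
from a multi-billion-token corpus with compiled human norms, which are
inherently out of reach of this package's inputs.

## Problem sizes and numerical choices

The shipped tests and the reproduction script run the pipeline at desk
scale — corpora of ~10⁴ tokens with vocabularies of ~10² words, norm
tables of 10²–10³ rows, 5,000-item parameter-recovery designs, 100-replicate
selection studies — sizes chosen so each check isolates one property with
comfortable statistical power. Exact-equivalence checks (brute-force
co-occurrence, exhaustive neighborhood cosines, Coltheart's N) use ≤ 500
tokens / ≤ 200 words where exhaustive enumeration is cheap. Noiseless
parameter recovery is asserted to 10⁻⁸; oracle equivalence to machine
precision; stochastic recovery within 3 SEs.

Degenerate inputs fail loudly by design: empty corpora, all-zero
matrices, zero vectors in cosine, vocabularies of one, zero-spread
z-scoring, empty post-filter trial tables, and out-of-bounds ratings all
raise typed errors naming the offender.
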