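# Methods

This note records the statistical model, the defaults and the numerical
choices behind `exoncorr`, and what the synthetic-data experiments do and do
not establish.

## Splicing quantification

For a cassette exon with inclusion pseudo-transcript FPKM `I` and skipping
pseudo-transcript FPKM `S` in one sample, the splicing level is the log
inclusion/skipping ratio

    e = ln((I + 1) / (S + 1)).

The +1 offsets keep the ratio finite at zero expression; `e = 0` when the two
transcripts are equally expressed, and the function is antisymmetric in its
arguments. Natural log is used; the base only rescales profiles and cancels
entirely under Z-normalization, but is fixed for reproducibility. FPKM values
are taken as given — no re-normalization is attempted, because the two
pseudo-transcripts of one exon share library and locus so most biases cancel
in the ratio.

The cassette filter keeps an exon iff `max_s I > 0` **and** `max_s S > 0`
over samples. Positivity is *not* required in the same sample: an exon that
is fully included early and fully skipped late is the clearest possible
cassette exon. Exons failing the filter are never alternatively spliced in
the data and are removed before any downstream step.

Pseudo-transcripts are built per internal exon from the flanks of one
canonical source transcript — the transcript with the most exons, ties broken
lexicographically by ID — a deterministic rule needed because an exon can be
internal in several transcripts with different neighbors. Left/right are
transcript (5′→3′) positions; features are emitted in genomic order per GTF
convention.

## LOESS smoothing of stage series

Splicing dynamics along development are assumed smooth, so stage-ordered
series are smoothed before association; a single-stage spike should not
create a stage-associated exon. The smoother is classical LOESS: at each
stage rank `t` (x-coordinates are ranks 1..n; no chronological-time axis is
assumed), the `q = max(degree+1, floor(span·n))` nearest stages receive
tricube weights `w = (1 − (d/d_max)³)³` and a local polynomial (degree 2 by
default, span 0.3) is fit by weighted least squares; the fitted value at `t`
is the smoothed value. No robustness iterations are applied.

Numerical notes:

- Because every exon shares the stage grid, the smoother is a linear operator
  `ŷ = L y`; `L` is built once per (n, span, degree) and applied to the whole
  exon × stage matrix. Rows of `L` sum to 1, so smoothing commutes with
  affine transforms of the series.
- If a neighborhood has fewer than degree+1 points with strictly positive
  weight (the q-th neighbor sits exactly at `d_max` and gets weight 0), the
  neighborhood is widened until the local fit is well-posed. With very small
  spans the local quadratic then interpolates — mathematically correct LOESS
  behavior, equivalent to no smoothing.
- Series shorter than degree+2 are returned unchanged with a warning.
- Tissue and cell samples carry no time order and are never smoothed;
  smoothing applies to the stage-ordered block only.

## Associated exons

Each exon's profile over the n samples of an analysis context is normalized
to Z-scores with the sample (n−1 denominator) standard deviation. Thresholds
are inclusive: HIGH at `z ≥ 1.5`, LOW at `z ≤ −1.5`; with an n−1 denominator
`|z| ≤ √(n−1)`, so for small n the thresholds bind conservatively.
Zero-variance profiles are uninformative: they are excluded from selection
but remain cassette exons and therefore remain in the overlap-test
population. Z-scores are computed within the sample universe of the map
being built (stage-only analyses normalize across stages only), so the
caller's matrix defines the context.

## The overlap test

Two samples are compared through their associated-exon sets.

*Within species*: the population is every cassette exon in both statuses
(2 × n_cassette items); the statistic is the number of (exon, status) members
shared — matching statuses are required. *Between species*: each of the M
conserved pairs contributes an *h* row and an *l* row (2M rows). F′ is the
set of rows whose fly exon is associated, in the row's status, with the fly
sample; W′ likewise; the statistic T counts rows in F′ ∩ W′. Row-level
semantics mean a one-to-many exon activates every row it occupies, which is
exactly what makes the 2M-row population internally consistent. With an
identity one-to-one pair table the between-species test reduces to the
within-species test bit-for-bit, which the test suite asserts on random
configurations.

The p-value is the hypergeometric upper tail

    p = Σ_{i=k}^{min(|A|,|B|)} C(n,i) C(n−i,|A|−i) C(n−|A|,|B|−i) / (C(n,|A|) C(n,|B|)),

evaluated entirely in log space (log-gamma binomials combined by
log-sum-exp), so mapping scores −log₁₀(p) remain finite at arbitrarily
extreme overlaps (verified against exact big-integer arithmetic at
population 4296 with sets of 1900). `k = 0` returns p = 1 exactly. Raw
scores are reported; no multiple-testing correction is applied across map
cells, since the map is read as a landscape rather than a list of discoveries.

Display ordering of tissue/cell axes uses agglomerative hierarchical
clustering (average linkage, Euclidean distance on score vectors, dendrogram
leaf order). Stage axes always keep chronological order.

## Negative controls and their calibration

The shuffle control re-pairs worm exons with fly exons: one uniform
permutation of the M pairs per shuffle, applied simultaneously to the h and l
rows so a pair's two rows travel together. The full between-species map is
recomputed per shuffle (default 100, seeded) and the per-cell mean and sample
sd are reported; the shuffled maps should be structureless.

For the *uniformity* diagnostic, a subtlety matters: the upper-tail p-value
of a discrete statistic is super-uniform under the null — `P(p ≤ α) ≤ α`,
with sawtooth deficits as large as the maximum pmf (here ≈ 0.05–0.1 per
cell) — so testing raw tail p-values against U(0,1) would reject for any
correct implementation. Calibration is therefore checked on the standard
randomized p-value `p* = P(X > T) + U·P(X = T)`, `U ~ Uniform(0,1)`, which
is exactly uniform under the null. Mapping scores themselves always use the
plain tail.

## The synthetic-data generator

`SimConfig` defaults define the standard evaluation regime: 20 fly and 24
worm stages, M = 2000 conserved pairs, 40% signal pairs, effect size 2.5
log-ratio units, additive stage noise sd 0.5, 5% one-to-many pairings, 10%
non-cassette exons, a two-segment piecewise-linear fly→worm correspondence
(each half of the fly axis sweeps the whole worm axis — the
"two parallel patterns" geometry), and a log-normal FPKM baseline with
log-mean 4 and log-sd 0.5.

Construction details:

- Each exon gets a constant per-exon baseline ratio (sd 0.5 across exons)
  plus i.i.d. additive noise per stage. Signal pairs add ±effect_size in a
  width-3 window (planted stage ±1, clipped at the axis ends) in both
  species at correspondence-linked stages; a 3-stage window survives span-0.3
  LOESS smoothing where a single-stage spike would not. HIGH and LOW planted
  statuses alternate, and planted fly stages cycle the stage axis so signal
  is balanced.
- FPKM pairs are derived from the target ratio: `S` is drawn log-normal and
  `I = (S+1)·e^ratio − 1`, clipped at 0, which makes the planted ratio exact
  under the pipeline's ratio definition. The log-mean of 4 keeps `S + 1`
  large enough that clipping of LOW-status windows (ratio ≈ −2.5) is rare.
- Non-cassette exons get `S ≡ 0` with log-normal `I`, so exactly
  `round(frac_non_cassette · M)` exons per species fail the cassette filter.
- One-to-many pairings duplicate a background worm exon across two fly
  partners. Reciprocal-fail pairs get a reverse-direction E-value above the
  cutoff; optional terminal-exon decoy hits pass reciprocity but fail the
  internal-exon requirement. All such planted counts are recorded in the
  truth table so each filter can be scored exactly.
- Signal pairs are always placed in orthologous genes, so the conserved
  (set a) table carries the planted correspondence; `frac_orthologous`
  controls how many background pairs join them.
- A small three-level term DAG is emitted; all signal genes share one term,
  giving enrichment a planted positive.

What the generator does **not** emulate: read-level noise and mappability,
transcript-level expression correlation between neighboring exons, realistic
exon sequence content, uneven stage spacing, and the real (much sparser)
signal density of genuine modENCODE-scale data. Passing the planted-recovery
tests shows the pipeline's inference machinery is correct and well
calibrated, not that real fly/worm stage alignments would reach any
particular score.

## Problem sizes and determinism

The evaluation experiments use the generator defaults (M = 2000, 44 samples
total, 100 shuffles), which exercise every code path at population sizes
comparable to the real study's 2148 conserved pairs while keeping the full
suite fast. All randomness flows through `numpy.random.default_rng` seeded
from a single configuration seed; a fixed seed reproduces byte-identical
bundle files and pipeline output hashes (asserted in the tests).

## Known limitations

- The cassette filter's per-transcript (not same-sample) positivity reading
  is the natural one for "alternatively spliced somewhere", but data where
  I and S are never co-positive in any sample will still pass it.
- Exons internal in several transcripts use one canonical flank pair;
  quantification against differently-spliced flanks is not modeled.
- KEGG-style flat term sets are supported, but the DAG depth filter then has
  nothing to act on.
- Annotation propagation to ancestor terms is not performed before
  enrichment; gene→term tables are used as given.
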