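# Methods

## Problem and scope

The package re-implements, as a tested pipeline, a re-analysis of two kinds
of *Drosophila melanogaster* expression data:

1. **Developing-testis microarrays** — per-transcript log2 intensities for
   ten biological replicates in each of seven developmental stages (feeding
   and wandering larvae grown 4–10 days, plus adults). The scientific
   question is whether X-linked expression falls below autosomal expression
   once meiotic spermatocytes dominate the tissue, as predicted by meiotic
   sex chromosome inactivation (MSCI), and whether the data are reproducible
   enough to detect such a difference at all.
2. **A tissue expression atlas** (FlyAtlas-style) — per-gene mean signals
   and four present/absent calls per tissue. The question is whether the
   apparent under-representation of tissue-specific genes on the X
   chromosome is a general property of tissue specificity, or a confound of
   tissue-specific sets being enriched with testis-biased genes, which are
   known to avoid the X.

## Two-channel records and exclusions

Two-channel records are reduced to M/A coordinates, M = R − G and
A = (R + G)/2, where R and G are normalized log2 channel intensities; all
statistics operate on A. Records with a missing channel have no A-value and
are excluded per stage — a gene dropped in one stage may remain in another,
because every statistic is computed stage-wise.

## Replicate QC

Pearson correlations are computed over genes for all 45 unordered pairs of
the 10 replicate arrays in each stage, on the log2 A-values (the
conventional array-QC choice, and the one that matches the intraclass
interpretation below). Pairs involving a constant column are undefined and
dropped rather than zeroed, which is conservative for the quality flag. The
pooled mean across stages is compared against a configurable benchmark
(default 0.9, the conventional threshold for a quality experiment).

Under the generating model below the expected pairwise correlation is
σ²_gene / (σ²_gene + σ²_error), which the test suite verifies by simulation.

## Variance decomposition

Within a stage, the decomposition is a one-way random-effects (nested)
design with genes as groups — the only nesting available within a stage:

- ss_within = Σ_g Σ_r (y_gr − ȳ_g)², ms_within = ss_within/(N − G)
- ss_among = Σ_g n_g (ȳ_g − ȳ)², ms_among = ss_among/(G − 1)
- var_within = ms_within; var_among = max(0, (ms_among − ms_within)/n₀)

n₀ is the effective group size: the replicate count for balanced data, the
Sokal–Rohlf correction n₀ = (N − Σn_g²/N)/(G − 1) when per-gene missing
replicates make the design unbalanced. A negative among-gene moment estimate
is clamped to zero, the standard variance-component convention; it keeps the
reported experimental-error fraction, 100·var_within/(var_within+var_among),
inside [0, 100]. No REML/ML fitting is attempted: the method is moment-based
by design.

The SD-ratio diagnostic divides the SD among genes of per-gene replicate
means by the mean over genes of the within-gene replicate SD, pooled and per
linkage class. Note two small biases a naive 1:1 expectation ignores: the
per-gene mean carries var_within/n extra variance, and the sample SD is
biased by the c₄ factor; at var_among = var_within and n = 10 the expected
ratio is √1.1/c₄(10) ≈ 1.08, which is what the tests assert.

## Chromosome contrasts

Per-gene expression in a stage is the mean of its replicate A-values; the
X-vs-autosome contrast is a two-sample t-test on these per-gene means.
Welch's unequal-variance form is the default (the safer choice when class
variances differ); the pooled-variance Student form and one-sided
alternatives are selectable, so results can be matched against analyses that
used either convention. Chromosome 4 counts as autosomal; arms outside
{X, 2L, 2R, 3L, 3R, 4} (Y, heterochromatin, mitochondrial, unmapped) are
excluded from linkage contrasts.

## Tissue specificity and sex bias

Ratio definition: a gene is specific to a focal tissue when the minimal
focal-to-other signal ratio across the denominator panel exceeds a fold
threshold (2, 5, 10 — nested by construction). Denominators are floored at a
configurable value (default 1 signal unit) before division, because atlas
signals are non-negative means and an unexpressed tissue would otherwise
produce infinite specificity. By default testis and ovary are not part of
the denominator panel when classifying somatic tissues (the panel
composition is configurable and recorded); this is what lets a
midgut-specific gene (e.g. signals 629 midgut / 196 testis / 34 ovary) carry
substantial testis signal — exactly the contamination the sex-bias filter
targets.

Presence/absence definition: specific to tissue T iff present in all four
replicate calls of T and absent in every call of every other tissue; at most
one tissue per gene by construction.

Sex bias partitions genes at a fold threshold (default 2): testis-biased iff
testis > 2·ovary, ovary-biased iff ovary > 2·testis, unbiased otherwise;
a both-zero gene is unbiased with an undefined ratio. The age filter keeps
genes predating the Sophophora/Drosophila subgenus split ("old"), removing
the known excess of young X-linked testis genes.

## Enrichment statistics

2×2 tables use Fisher's exact test when the total count is below 5,000 and
the 1-df Yates-corrected chi-square otherwise. The two-sided Fisher p-value
is the sum of probabilities of all fixed-margin tables whose probability
does not exceed the observed table's — implemented by exact integer
enumeration of the hypergeometric weights, so ties are handled without a
floating-point guard (the convention of the common statistical environments,
against which the tests cross-check). The Yates statistic uses the clamped
correction max(0, |ad − bc| − N/2). A zero margin yields p = 1 with a
degeneracy flag. Raw p-values with star thresholds (0.05/0.01/0.001) are
reported without multiplicity correction, matching the analysis style the
pipeline reproduces; a Benjamini–Hochberg column can be added by the caller.

The normalized X frequency of a gene set is f = p̂/p₀ with p̂ the set's
X-linked fraction and p₀ the genome fraction; its standard error is the
binomial SE of p̂ divided by p₀ (p₀ treated as fixed, since the genome is
orders of magnitude larger than the sets). f ± 1 SE is a ~70% band and
f ± 2 SE a ~95% band — the reason one-SE bars routinely overlap even when a
test rejects. Enrichment tables use the rest of the genome (genome minus the
set) as background; with sex-bias filtering enabled, non-unbiased genes are
removed from both the set and the background before testing.

## Synthetic data generator

Stage matrices: gene baselines μ_g ~ Normal(8, √var_among) log2 units; stage
means add an X-only shift; replicates add Normal(0, √var_within_s) noise.
Defaults are the study conditions: 14,000 transcripts × 10 replicates ×
7 stages; per-stage var_within values (0.42, 0.50, 0.33, 0.31, 0.36, 0.47,
0.79 against var_among = 1) chosen to span experimental-error fractions from
~24% to ~44% with a pooled replicate correlation near 0.70; X fraction 1/6
(the approximate euchromatic share of the X); a −0.5 log2 X shift in the
three late stages, a detectable-but-modest effect consistent with partial
silencing diluted by somatic cells.

Tissue panel: per-gene baseline signals are log-normal (ln-mean ln 400,
ln-SD 0.8) with per-tissue log-normal scatter (ln-SD 0.75); planted
tissue-specific genes get focal signal = fold·(1+margin)·max(other panel
signals), so they exceed the planted fold strictly. With probability
`sexbias_coupling` a planted somatic-tissue gene is additionally made
testis-biased (ovary signal reduced to testis/r, r ~ U(2.5, 8)), and such
coupled genes draw their chromosome with a depleted X probability —
the confound the filtering analysis must remove. Planted testis-specific
genes are preferentially autosomal and ovary-specific genes preferentially
X-linked at configurable strength.

Presence/absence calls are thresholded (default 50 signal units) from the
per-gene baseline plus the planted single-tissue patterns, with optional
Bernoulli flip noise per replicate call (default 0.01). Driving calls from
the baseline makes background genes broadly present or broadly absent; a
model thresholding the per-tissue signals directly would let
threshold-straddling background genes produce chance single-tissue presence
patterns, contaminating the planted truth. This is a deliberate
simplification: real atlases contain genuinely narrow-breadth background
genes, so presence/absence results on real data will include candidates the
generator never produces.

What passing tests show — and do not show: the generator draws independent
Gaussian/log-normal noise with no probe effects, no correlation between
tissues beyond the shared baseline, no intensity-dependent variance and no
annotation errors. Recovery and calibration results therefore validate the
estimators and the end-to-end logic, not the biology of any particular real
dataset.

## Numerical and design choices

- Gene-level signal from multiple unique probes: mean of signals; calls from
  the most intense probe. Probes without a unique genome alignment are
  dropped at load (configurable).
- Multiple transcripts per gene are kept as separate rows (transcript-level
  keys), matching the keyed input format.
- Fisher enumeration is exact integer arithmetic; at the N < 5,000 boundary
  the support never exceeds ~2,500 terms, so the exact path stays fast.
- Stochastic assertions in the test suite are frequencies over fixed seed
  batches with tolerances derived from the binomial SD of the estimate, not
  single-seed point checks.
- Problem sizes in tests and the acceptance script (1,200–14,000 genes,
  100–1,000 simulation replicates) were chosen to keep Monte-Carlo error
  well inside each stated tolerance.

## Known limitations

- The published study's own headline numbers (per-stage error percentages,
  the 0.72 pooled correlation, the adult SD ratio 1.1, the late-stage
  p-values) derive from its deposited normalized-expression table, which is
  not redistributable here; the reproduction path is implemented
  (`tests/test_acceptance.py::test_deposited_study_table_reproduction`) and
  activates when that table is placed under `data/`.
- No raw-chip normalization, dye-bias or spatial diagnostics: inputs are
  already-normalized values.
- No expression-breadth indices (e.g. tau) beyond the two specificity
  definitions; no permutation or regression-based enrichment alternatives.
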