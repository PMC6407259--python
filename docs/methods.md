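# Methods

This note documents the models, numerical choices and design decisions
behind `arraycnv`, and what the synthetic-cohort tests do and do not
establish about behaviour on real hybridization data.

## Signal model

A two-colour CGH array measures, per probe, the log2 ratio of test to
reference intensity. After normalization the working model is

    x_ij = log2(cn_ij / 2) + s_j + e_ij,      e_ij ~ N(0, σ_probe²)

for probe *i* in sample *j*, where `cn` is the absolute copy number in the
test sample (the reference contributes two copies), `s_j` is a small
per-sample baseline shift and `e` is probe-level noise. Copy number 0 is
a true −∞ on this scale; the simulator emits it at a documented floor of
−4 to keep arithmetic finite, and the segmenter treats it like any other
level. Male samples hybridized against a female reference are hemizygous
for chrX, so their chrX baseline is log2(1/2) = −1; the pipeline recentres
male chrX at its own median so that chrX CNVs deviate from 0 like
autosomal ones.

The Gaussian noise assumption is the standard working model for normalized
aCGH log ratios and is what makes the calling thresholds analyzable (see
below); the instrument's true noise spectrum (spatial artifacts, dye bias,
GC waves) is explicitly out of scope.

## Segmentation

Each sample × chromosome profile is segmented by minimizing

    Σ_segments Σ_probes (x − mean_segment)²  +  λ · (#segments)

exactly, via the Bellman recursion over candidate last-changepoints
(O(n²) per profile; an optional maximum-segment-length band gives
O(n·band) for very long profiles, as an approximation). Ties in the
recursion break toward the earlier changepoint candidate, making the
output deterministic. Missing probes are dropped from the fit but kept in
the span bookkeeping so segments always tile the probe index range.

When λ is not fixed, it is selected per profile from a candidate grid
(default 0.05–3.2, geometric) by the classical changepoint BIC

    n·ln(SSE/n) + 2k·ln(n)

with **two** parameters per segment (its mean and its boundary). A
one-parameter count systematically oversegments pure-noise profiles at
σ_probe = 0.15 (keeping a single segment in only ~63% of replicates,
versus ≥ 97% with the two-parameter count), so the two-parameter form is
used. The segment-count-vs-penalty relation is monotone, which the tests
exploit as a property check, and DP optimality is verified against
exhaustive enumeration of all 2^(n−1) segmentations for profiles up to
length 12.

Pipeline runs use a fixed λ = 0.26 ≈ 2σ²ln(n) for σ = 0.15, n ≈ 5,000 —
the asymptotically motivated scale for one expected changepoint under the
noise model — rather than per-profile selection, for speed and
reproducibility.

## Calling and CNVR construction

A segment becomes a CNV call when |mean log2| ≥ 0.5 across ≥ 5 consecutive
probes (the `0.5_5` rule); adjacent qualifying segments of the same sign
merge into one call with a probe-weighted mean, and sub-threshold gaps are
*not* bridged. Calls are then filtered to 1 kb < length < 5 Mb with strict
inequalities (boundary lengths removed). Under the noise model the 0.5_5
rule's per-window false-positive probability is ≈ (2Φ(−0.5/0.15))^5 ≈
10^-18, which is why self-to-self (noise-only) hybridizations yield zero
calls — a property the tests and acceptance script measure directly.

CNVRs are connected components of calls under ≥ 1 bp overlap (1-based
inclusive coordinates throughout; interval length = end − start + 1; only
BED serialization is 0-based half-open). Bookended calls do not merge.
Regions are classified loss / gain / both and identified in genomic order.
Unplaced (chrUn-like) sequence is accepted but excluded from association.

## Association

Per CNVR, member-probe log2 ratios collapse to one score per sample via
the first principal component, oriented to correlate positively with the
mean member-probe signal (a single-probe CNVR's score is that probe's
row). A univariate Gaussian mixture with k ∈ {1, 2, 3} components is
fitted by EM: deterministic quantile initialization plus 5 seeded random
restarts, tolerance 1e−8 on the log-likelihood, at most 500 iterations,
component SD floor 1e−3. k is chosen by BIC among *admissible* fits — no
component SD clamped at the floor, every weight ≥ 2/n — because a
singleton component at the SD floor is a likelihood spike, not a copy
class; if no fit is admissible the raw BIC winner is kept and flagged.

A fit counts as **converged** when EM converged, all weights ≥ 2/n,
adjacent component means are ≥ 0.5 pooled SDs apart, and k ≥ 2. A
1-component pick on non-degenerate scores means the CNVR's copy classes
could not be resolved and the CNVR is excluded from testing; truly
degenerate (zero-variance) scores are a trivially converged baseline.
This operational definition of convergence is the package's own — the
upstream literature reports *that* loci fail to converge without defining
the criterion.

Mean-sorted components map to genotype classes {1, 2, 3} (1 = lowest
signal). With two components the larger-weight component is the modal
baseline class 2 and the other is 1 or 3 by mean; a weight tie resolves
toward the component nearer the score median. Regression uses the
posterior-expected dosage by default (hard class labels behind a flag):
expectation is robust to assignment uncertainty near class boundaries.

Each converged CNVR × trait pair is tested by OLS of the PTA on dosage;
the two-sided p comes from the slope t statistic. Bonferroni correction
uses, by default, the per-trait family m = number of converged CNVRs
(configurable to global m × #traits; the literature is ambiguous between
the two). Variance explained is reported as the squared Pearson
correlation between the one-dimensional CNVR signal and the trait — the
definition used in CNV association practice — while the regression's own
r² (dosage vs trait) is checked separately as the OLS identity. PTA
reliabilities are read but unused by default; optional weighted least
squares sits behind a flag. No kinship/mixed-model correction is applied:
PTAs are already additive genetic predictions with fixed effects removed.

Trait clustering transforms the CNVR × trait p matrix to −log10 p, uses
1 − Pearson r between trait columns as the distance, and average linkage;
a constant column is placed at the maximal distance (2.0) with a warning.

## Synthetic cohorts: what they emulate, and what they do not

The generator reproduces the study conditions this pipeline targets:
~1.2 kb mean probe spacing (uniform grid with ±25% jitter; only the mean
interval is specified by array designs), cohorts of 47 male samples
against a female reference, planted gain/loss segments spanning a few kb
to Mb with copy numbers in {0, 1, 2, 3, 4}, self-to-self noise-only
controls, and 41 PTA traits in four correlated blocks
(production 6 / reproduction 9 / health 8 / type 18, within-block
residual correlation 0.6). Defaults: σ_probe = 0.15, per-sample shift SD
0.05 — chosen for testability (the recall and false-positive properties
are analyzable at that level), not as a claim about any instrument.
Phenotypes follow trait = Σ β·(cn − 2) + correlated residual, so a locus's
expected variance explained is β²Var(D)/(β²Var(D)+σ²) in closed form, and
effect sizes can be designed to hit a target fraction exactly.

All randomness flows from one integer seed through a named
`SeedSequence` splitting scheme; every simulator output is byte-identical
across runs with the same seed.

Passing tests on these cohorts establish algorithmic correctness (exact
DP optimality, rule fidelity, oracle agreement) and statistical
calibration under the stated model. They do not establish robustness to
spatial artifacts, wave effects, probe-response heterogeneity or
reference-sample idiosyncrasies in real hybridizations — all of which are
upstream normalization concerns out of this package's scope.

## Problem sizes and evaluation design

The simulation studies in `arraycnv.studies` run at desk scale, chosen as
the smallest sizes at which the measured quantities are meaningful:
segmentation optimality is exhaustive only up to 12 probes (where full
enumeration is feasible); genotyping accuracy uses the canonical three
clusters at −1 / 0 / +0.585 with SD 0.05 at n = 150; calibration uses
1,000 null replicates at the cohort size n = 47; end-to-end power uses
200 replicates of a 300-probe chromosome carrying one 20-probe CNVR whose
dosage (copy numbers 1/2/3 at 0.3/0.4/0.3) explains 20% of one trait's
variance — a value chosen by closed-form power analysis so that a
properly functioning pipeline detects it with power ≈ 0.9 at
Bonferroni-corrected 0.05, while leaving headroom to distinguish genuine
power loss. The packaged demo plants its headline effect at 30% variance
explained for the same reason: at n = 47 with a ~30-CNVR family, a 15%
effect sits near the detection boundary (and indeed fails correction in
the demo), which the demo deliberately exhibits.

## Known limitations

- The segmenter is exact for the penalized least-squares objective but is
  not a reimplementation of any vendor tool's scoring; proprietary
  model-selection rules are unknown and not claimed.
- The banded DP option trades exactness for speed on very long profiles.
- Genotype classes are capped at three; high-amplitude multi-allelic CNVs
  (cn ≥ 4 segregating alongside losses) fold into the nearest class.
- The association model is a simple regression on dosage; it does not
  integrate over genotype uncertainty via a full likelihood-ratio
  machinery, nor correct for relatedness.
- QTL "support" uses the union of retained QTLs over a region (the
  conservative reading of coverage); per-QTL best coverage is available
  from the per-record fractions.
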