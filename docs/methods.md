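# Methods

## The statistical model

The pipeline treats a cohort as a tidy table: one row per animal with
group ∈ {sham, injured}, sex ∈ {male, female}, one of an ordered set of
timepoint labels (defaults 1h, 6h, 1d, 3d, 7d, carrying numeric hours
1, 6, 24, 72, 168), and numeric feature columns that may contain missing
values. Animals are sacrificed at their timepoint, so the design is
cross-sectional per timepoint with independent animals across cells —
the trajectory statistics below need no within-animal correlation model.

### Per-timepoint tests and Fisher combination

For a binary contrast (labels A, B of one metadata column, optionally
within a filter such as group = injured), each timepoint with at least
`min_n` observed values per arm (default 2) contributes a two-sided
Mann–Whitney U test on the observed values. The exact permutation null
of U is used whenever the pooled sample has ≤ 16 values and no ties —
cells of 4–10 animals make the normal approximation crude — and the
exact CDF is computed once per (n₁, n₂) by the standard counting
recurrence and cached. Larger or tied samples use the normal
approximation with tie and continuity corrections; both routes agree
with scipy's `mannwhitneyu` to machine precision (tested).

Usable timepoints' p-values combine as Ψ = −2 Σ ln pᵢ with df = 2k;
the analytic combined p is the upper χ²₂ₖ tail at Ψ. p-values below
10⁻¹⁵ are clamped to 10⁻¹⁵ before the log (and counted in the result)
so Ψ stays finite. Two-sided tests are used throughout: the scientific
question is "do the sexes differ", not a directional hypothesis.

Because the per-timepoint p-values are discrete (exact doubled-tail
p-values on small samples are super-uniform), the analytic combination
is slightly conservative: at k = 5 and 8 + 8 animals per timepoint the
true rejection rate at α = 0.05 is ≈ 0.036 rather than 0.050. The
permutation combined p (below) is the calibration-free companion.

### Permutation null

Contrast labels are shuffled independently within each timepoint
stratum (group and timepoint fixed), the full per-timepoint-test +
Fisher pipeline is recomputed, and

p_perm = (1 + #{Ψ_perm ≥ Ψ_obs}) / (1 + n_perm)

(add-one estimator, never exactly zero). With complete observations the
per-permutation test is a rank-sum over a re-labelled pooled sample, so
ranks and tie structure are computed once per stratum and only label
assignments vary — mathematically identical to re-running the test, but
vectorized over permutations. When a stratum has missing values,
shuffled labels change the observed arms' sizes, so that stratum falls
back to per-permutation evaluation; permutations where an arm drops
below `min_n` treat the timepoint as skipped (contribution ln 1 = 0),
the same rule applied to the observed data. A stratum whose labels are
all identical contributes no variation; if every stratum is degenerate
the permutation p is undefined and an error is raised.

### Directional consistency

At each usable timepoint the sign of (mean_A − mean_B) is recorded,
with |difference| < 10⁻¹² treated as sign 0. The majority direction is
the nonzero sign with the strictly larger count; consistency is the
fraction of usable timepoints matching it. Zero signs never match; on a
+/− tie (or all zeros) there is no majority and the reported fraction is
the tied count over k, which lands at 0.5 for an even split. For
trajectory plots the cumulative variant — consistency over timepoints
1..t for each t in chronological order — is exported alongside; the
headline number is always the full-window fraction, and the report
metadata names the variant.

### Imputation

Missing cells are filled per variable within each group × sex ×
timepoint subset: with ≥ 2 observed values the missing cells receive
the subset's arithmetic mean; with fewer they stay missing, unless the
caller sets the global-mean fallback, intended only for consumers that
need complete columns (PCA composites, the embedding, a fully defined
correlation matrix). Observed values are never altered, so subset means
are invariant and re-imputation is a no-op. Features missing in
strictly more than 70% of animals are dropped before imputation.
Binary-coded physiological features are imputed like any numeric column
(their subset means may be non-integral); the imputation log records
every action per cell.

### Correlation structure and modules

Spearman correlations are pairwise-complete over animals with average
tied ranks; entries with fewer than `min_pairs` (default 3) overlapping
observations, or a constant variable on the overlap, are undefined and
flagged. Clustering requires a fully defined matrix — the intended
resolution is re-running after global-mean fallback imputation.
Features are clustered agglomeratively with average linkage (UPGMA) on
the Euclidean distance between rows of the ρ matrix (the literal
reading of clustering "on the correlation matrix"; the conventional
1 − ρ dissimilarity is available behind a switch). The dendrogram's
leaf order arranges the heatmap; a flat cut proposes modules. The cut
is advisory: module membership is a curation decision supplied through
configuration, and singleton clusters are flagged since a composite
needs ≥ 2 members.

### PC1 composites

Module members are standardized to mean 0 and sample SD 1 (n − 1
denominator, the standard PCA preprocessing) over observed values; the
composite score is the projection of complete-member animals (≥ 3
required) onto the leading eigenvector of the member covariance. The
principal axis has no intrinsic sign, so the orientation convention
fixes it: scores must correlate positively with the row-mean of the
standardized members. This anchors the composite to the members' common
direction — negating every member therefore negates the scores, and
"higher composite" always reads as "members jointly higher". Animals
missing a member after subgroup imputation are dropped by default or
rescued via the global-mean fallback flag.

### Embedding

Only animals complete on the selected features (default: the module
scores) are embedded. Features are standardized, and t-SNE runs with a
seeded PCA initialization scaled to the conventional 10⁻⁴ spread —
random initialization would make figures irreproducible. Default
perplexity is min(30, ⌊(n − 1)/3⌋) and an explicit perplexity must
satisfy n ≥ 3·perplexity + 1. The published-figure convention is kept:
color = sex, marker = group, numeric timepoint labels.

### Evans-Blue metrics and decay

Extravasation is the count of ROI pixels with intensity strictly
greater than 100 (the calibrated threshold; a pixel at exactly 100 does
not count), with the area fraction over the ROI size; integrated
density is the plain intensity sum over the ROI. ROI membership is
full-pixel, row-major, origin top-left. Intensities are accepted as
reals — 8-bit quantization is not assumed.

The leakage time course is fit by
y(t) = P + A_fast·e^(−k_fast t) + A_slow·e^(−k_slow t). The rate
ordering k_fast > k_slow > 0 is enforced smoothly by k_slow = e^θ¹,
k_fast = k_slow + e^θ², which removes label switching between phases.
For fixed rates the model is linear in (P, A_fast, A_slow), so the
amplitudes are profiled out at every step by bounded linear least
squares (amplitudes ≥ 0 — this is a decay model, so strictly growing
data pins an amplitude at zero and sets the boundary flag rather than
fitting growth with negative amplitudes); θ is optimized by
Levenberg–Marquardt from a multistart grid of rate pairs spanning
(4·max t)⁻¹ to 4/min t geometrically. The nested single-phase fit is
returned for comparison and, because a single-phase solution is a
boundary case of the two-phase model, the two-phase RSS is guarded to
never exceed it. The fit is scale-equivariant: scaling y by c > 0
scales (P, A_fast, A_slow) by c and leaves the rates unchanged.

## The synthetic cohort generator

The generator emulates the study design the pipeline assumes: 2 groups
× 2 sexes × 5 timepoints, `n_per_cell` animals per cell (default 8,
i.e. 16 per group per timepoint, inside the 10–20 animals/group/
timepoint range of such designs). Features come in blocks sharing one
latent standard-normal factor each:

x_j = √ρ·z + √(1 − ρ)·ε_j + shift(group, sex, timepoint)

so within-block correlation is exchangeable at ρ, between-block
correlation is zero, and shifts are in marginal-SD units when
noise_sd = 1. Physiological scalars (apnea duration, righting time,
weight change) share one weak factor (loading 0.1) so they cluster
loosely, reproducing the reduced clustering such measures show relative
to imaging blocks. Missingness is applied last, missing-completely-at-
random over feature cells at rate 0.17 by default (capped at 0.5);
MCAR matches the subgroup-mean imputation's assumptions, and a single
global rate is used because per-feature rates are not part of the
design being emulated. Identical config + seed reproduces the table
exactly; the missingness sub-seed is derived from the config seed.

The default effect template encodes the qualitative injury pattern the
analysis is meant to resolve — vascular blocks depressed in injured
males acutely (−1.5 SD at 1 h) recovering by 7 d, EB leakage elevated
early in both sexes with a faster female decay, LFD mildly elevated in
injured males, shams never shifted. It is a test harness, not ground
truth, and is fully overridable. Canonical scenario builders fix the
study conditions used by the validation suite: `null_config` (no
effects anywhere), `constant_direction_config` (+1.5 SD male shift at
every timepoint), `alternating_direction_config` (noiseless ±shift
alternation, giving deterministic signs +,−,+,−,+),
`two_block_config` (two ρ = 0.8 blocks of 4, 500 animals), and
`strong_separation_config` (3-SD module shifts between the injured
sexes).

### What the generator does not emulate

Real cohorts have heavier-tailed and skewed features (areas,
densities), missingness that may correlate with injury severity (MNAR),
shams shared across sacrifice cohorts rather than drawn independently
per timepoint, and between-block correlations that are small but not
zero. Passing tests therefore demonstrate that the pipeline recovers
the structure it assumes when that structure is present, and that its
null calibration holds under exchangeability — not that the biological
conclusions of any particular animal study are correct.

## Numerical choices

- Exact MWU switch at pooled n ≤ 16 without ties; the exact null CDF is
  cached per (n₁, n₂).
- p-value clamp at 10⁻¹⁵ before logs; clamped values counted.
- Sign tolerance 10⁻¹² for mean differences.
- Dendrogram tie-breaking follows scipy's deterministic leaf ordering,
  so results are reproducible across runs.
- t-SNE determinism comes from the seeded PCA init plus fixed
  `random_state`; coordinates are bitwise reproducible on one platform.
- Decay-fit multistart uses a 6-point geometric rate grid (all ordered
  pairs) and |log-rate| capped at 30 to keep exponentials finite.
- The permutation p uses the add-one estimator; n_perm ≥ 100 enforced.

## Problem sizes in the validation suite

The simulation studies run at the sizes the desk-scale checks call for:
1000 null cohorts for type-I calibration, 200 cohorts × 500
permutations for permutation/analytic agreement, 200 replicates for
consistency recovery, 50 replicates of 500-animal two-block cohorts for
module recovery, and 10 seeds for the embedding silhouette. The full
suite completes in well under a minute of compute for the statistical
checks; end-to-end pipeline runs on the default 160-animal cohort take
a few seconds each.

## Known limitations

- The hierarchical imputation reduces within-subset variance (imputed
  cells sit exactly at the subset mean); downstream tests on heavily
  imputed features are anti-conservative in principle. The trajectory
  tests mitigate this by running on observed values only.
- Fisher's method assumes independent per-timepoint p-values, which
  holds here by design (different animals per timepoint) but would not
  under repeated measures.
- The analytic combined p inherits the conservatism of discrete exact
  p-values (see above); the permutation p does not.
- Consistency is undefined in direction (majority sign `None`) on exact
  sign ties; the reported fraction remains informative but the
  trajectory plots should display the tie explicitly.
- propose_modules is advisory; an automatic flat cut can split a true
  block or merge blocks when effects induce cross-block correlation
  (injury shifts shared across blocks correlate their features).
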