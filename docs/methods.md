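# Methods

This note documents the models, conventions and design choices behind
`mycstrat`, in the order the pipeline runs them.

## Synthetic cohorts: what is emulated, and what is not

The generator (`mycstrat.synthetic`) produces the statistical skeleton of a
PDAC-style cohort study:

- **Expression.** Genes × samples on a centered log2-intensity scale.
  Background values are i.i.d. Normal(0, `noise_sd`); the union of the three
  MYC-target signature genes is shifted by `effect_size × noise_sd` in the
  MYC-high samples. Defaults: 1000 genes, `noise_sd = 1`, `effect_size = 1.5`
  SD — a coordinated but individually noisy shift, the regime in which
  averaging over a 50-gene signature is informative while single genes are
  not.
- **MYC-high fraction.** Exactly `round(frac_myc_high × n_samples)` samples,
  default 10% — the prevalence at which this subtype is described (8 of ~80,
  15–16 of 150).
- **Signatures.** Three sets of 50 genes; a core of
  `signature_overlap × 50 = 10` genes is drawn first and shared by all three,
  matching the real situation in which MYC-target signatures overlap
  substantially.
- **Survival.** Exponential event times with baseline hazard 1/600 per day
  (median ≈ 416 days in the low group, a realistic PDAC scale), multiplied
  by `hazard_ratio` (default 2) in the high group. Administrative censoring
  at a fixed horizon chosen so ~30% of low-group samples are censored
  (h = −ln 0.3 / λ ≈ 722 days), configurable.
- **Subtype.** A binary squamous-like label drawn at probability 0.8 in the
  high group versus 0.2 elsewhere.
- **Screen.** Works in *response* space (response = 100 − viability). Non-hit
  drugs elicit the same mean response (default 30%) in both groups; hit drugs
  multiply the MYC-high response by `hit_ratio` (default 2.5, which must keep
  the response ≤ 100%). Replicate noise is multiplicative with a configurable
  CV; with CV = 0 the ratio statistic recovers the planted configuration
  exactly, which is the basis of the exact-recovery tests.

What the generator does **not** emulate: gene–gene correlation beyond the
planted block, count-level RNA-seq noise, batch effects, platform
differences between cohorts, or any relationship between expression and
survival other than the group label. Passing tests therefore demonstrate the
correctness and calibration of the statistics under their own assumptions,
not robustness to the full messiness of consortium data.

All generators are pure functions of (config, seed); the pipeline derives
per-stage seeds from a single master seed via `numpy.random.SeedSequence`.

## Consensus classification

For each signature the matrix is restricted to the signature genes present
(absent genes are dropped, not imputed, so human signatures can be applied
to murine data with `case_fold=True`), each gene row is scaled to zero mean
and unit variance (sample SD; zero-variance rows dropped with a warning),
and samples are clustered by agglomerative Ward clustering on Euclidean
distance — the ward.D2 criterion, i.e. `scipy.cluster.hierarchy.linkage(X.T,
"ward")`, stated explicitly so R `hclust(method="ward.D2")` ports agree.

The tree is cut at `k` clusters (default **k = 2**: the method is a
high/low dichotomy; k is exposed rather than auto-selected). The MYC-high
cluster is the one with the largest mean row-scaled signature expression.
An optional *secondary-inclusion rule* also admits any other cluster whose
mean scaled expression exceeds a threshold t (default t = 0, rule off by
default): this generalizes the manual judgement call of including a cluster
with incompletely elevated target genes, turning it into a reproducible
parameter. Exact ties in cluster means break deterministically toward the
cluster containing the lexicographically smallest sample ID, with a warning.

The consensus MYC-high set is the plain intersection of the per-signature
high sets; pairwise and triple overlap counts are reported for Venn-style
summaries. An empty consensus is a valid (warned) result.

## GSEA engine

- **Ranking.** Signal-to-noise: s(g) = (μ⁺ − μ⁻)/(σ⁺ + σ⁻) with each class
  SD floored at max(0.2·|μ|, 0.2) (the Broad convention). If a class has
  fewer than 2 samples the score falls back to the difference of means with
  a warning. Ties break by gene ID ascending (genes are pre-sorted by ID and
  the score sort is stable), so rankings are platform-independent.
- **Enrichment score.** Walking the ranking, hits add
  |s|^p / Σ_hits |s|^p (p = 0 → 1/N_H) and misses subtract 1/(N − N_H);
  ES is the running sum's value at its maximum absolute deviation. The
  extremum search admits a 1e-10 tolerance so that deviations equal in exact
  arithmetic (an early −x and a later +x) resolve to the first occurrence,
  matching exact-rational enumeration — this is what the exhaustive oracle
  test checks for every proper subset of lists up to length 12. The leading
  edge is the hit genes at or before the extremum (at or after it for
  negative ES). A set covering the whole ranked list is an error (the miss
  penalty is undefined), as is an empty overlap.
- **Permutation null.** `perm_type="auto"` permutes phenotype labels when
  both classes have ≥ 7 samples and resamples random gene sets of equal size
  otherwise; both modes can be forced. Phenotype permutation re-ranks all
  genes per permutation (vectorized over the permutation axis). Default
  `n_perm = 1000`.
- **p, NES, q.** Nominal p uses add-one smoothing, (b+1)/(m+1) over the
  same-signed null ES, so p is never 0. NES divides ES by the mean |null ES|
  of matching sign. FDR q is the standard GSEA tail-ratio over pooled
  normalized scores, clamped to [0, 1] and monotonized within each sign by a
  step-up (suffix-minimum) pass. BH and BY step-up adjustment are provided
  separately for the unweighted enrichment path.
- **Sizes.** `min_size = 5`, `max_size = 500` — permissive defaults suited to
  synthetic collections (the common tool defaults are 15/500).

Null calibration is asserted empirically: on zero-effect cohorts the nominal
p of a random gene set is uniform (KS test over 200 independent runs). The
add-one smoothing biases p upward by ~1/(2 n_perm), which is negligible at
the tested n_perm.

## Drug-screen statistics

- **Hit rule.** response = clamp(100 − viability, 0), replicates averaged
  first (missing wells excluded with the effective n recorded); ratio = mean
  high-group response / mean low-group response; **hit ⇔ ratio > 2**; drugs
  ranked by descending ratio with ID tie-break. The rule is defined on
  response, not viability: a drug that kills MYC-high lines preferentially
  raises their response and the ratio; on viability the inequality would
  invert. When the low-group mean response falls below ε = 1 percentage
  point the ratio is computed against ε and flagged unstable (inert drugs in
  resistant lines would otherwise explode the statistic).
- **4PL fit.** v(d) = bottom + (top − bottom)/(1 + (d/GI50)^hill), fitted by
  bounded least squares on log10 dose (bottom ≥ 0, hill ∈ [0.1, 10]),
  initialized at top = max v, bottom = min v, GI50 = dose nearest the
  half-range crossing, and restarted from hill ∈ {0.5, 1, 3} to escape local
  minima; tolerances 1e-12. Both the *relative* GI50 (inflection) and the
  *absolute* GI50 (dose where fitted viability crosses 50% of control) are
  reported, the latter censored at the maximum tested dose when the curve
  never crosses — the two differ whenever bottom/top are not 0/100, and
  "nonlinear regression GI50" does not by itself disambiguate them.
- **AUC.** Trapezoidal integral of viability/100 (clipped to [0,100]) over
  log10 dose, normalized by the log-dose span → [0, 1], invariant to
  rescaling all doses; duplicate doses are averaged first.
- **Quartile phenotype.** Boundary at the linear-interpolation (type-7)
  quantile — stated so R and Python agree — with boundary ties included in
  the sensitive set; the complement becomes the comparison class for
  enrichment.
- **Correlation.** Pearson r on log10 GI50 (potencies are log-normal), with
  the two-sided t-transform p and the least-squares line.

## Survival and association statistics

Kaplan–Meier estimation and the two-group log-rank test (1 df) are delegated
to lifelines; the conventions that matter are stated and tested: censored
observations tied with an event time count as at risk at that time
(event-before-censor), S(0) = 1, no continuity corrections. Time units in
the synthetic data are days.

The two-sided Fisher exact test uses the probability-mass definition — the
sum of hypergeometric probabilities of all same-margin tables no more
probable than the observed one — implemented by direct enumeration with a
1e-12 relative tie tolerance. Two-sided Fisher has competing definitions, so
one is fixed and tested against exact-rational enumeration for every 2×2
table with total ≤ 30. (The minimum analytic gap between distinct pmfs at
n ≤ 30 is ~1/C(30,15) ≈ 6×10⁻⁹, far above both float error and the
tolerance, so the comparison is robust.) A zero margin returns p = 1 by
convention. ΔΔCt fold changes are 2^−ΔΔCt against a housekeeping gene and a
reference sample whose fold is exactly 1.

### Power of the survival comparison

With 10% of samples in the high group, a hazard ratio of 2 and ~30%
censoring, the Schoenfeld approximation gives
z ≈ ln 2 · √(D·p·(1−p)) ≈ 1.7 at n = 80 (D ≈ 58 events, p ≈ 0.1), i.e.
power ≈ 0.45 at α = 0.05 — below a coin flip no matter the censoring
configuration, because the imbalance, not the follow-up, is binding. The
test suite therefore asserts a majority rejection rate at n = 150 (measured
≈ 0.68) and a clearly-above-null rate (≥ 0.3) at n = 80. A single cohort of
80 with a 10% subgroup should not be expected to show significant survival
separation even when the effect is real.

## Pipeline and reproducibility

`run_full_analysis` executes simulate → classify → consensus → GSEA
(consensus vs rest, planted signatures + decoy sets drawn from
non-signature genes) per cohort → cross-cohort intersection at q < 0.25 →
screen scoring (4-line panel, 2 high / 2 low) → per-line 4PL fits on a
40-line panel → sensitivity-quartile GSEA → log-rank and Fisher tests. The
report is a versioned, JSON-serializable dict whose provenance block (seed,
full config, config hash, package version) suffices to reproduce the run;
serialization sorts keys so identical runs are byte-identical. Stage timing
goes to logging, never into the report.

Default problem sizes (1000 genes, cohorts of 80/150, n_perm = 1000,
129-drug screen, 40-line panel) keep a full run in a few seconds on one CPU
while leaving every statistic in its intended operating regime; the null
calibration and type-I-error studies use reduced sizes (200 genes / 40
samples; n = 40 per arm) chosen so the permutation and simulation loops
stay fast without changing what is being asserted.

## Known limitations

- The classifier's k and the secondary-inclusion threshold are parameters,
  not estimates; nothing selects them automatically.
- The GSEA q-value is the tool-convention tail ratio, not a BH-adjusted
  p-value; with few gene sets it is coarse (granularity 1/n_sets on the
  observed side).
- The 4PL fitter reports non-convergence rather than failing, but does not
  attempt profile-likelihood intervals for GI50.
- The synthetic cohort's independence assumptions make classification easier
  than on real data at the same effect size; recovery rates here are upper
  bounds, not field estimates.
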