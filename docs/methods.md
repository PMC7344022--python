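# Methods

## Sample entropy

The core statistic is sample entropy: for a series x of length N,
templates u_i = [x_i, …, x_{i+m−1}] are compared under the Chebyshev
(component-wise maximum) distance, counting ordered pairs (i ≠ j) within
tolerance r for windows of length m (count B) and m+1 (count A), and
SampEn = −ln(A/B). Conventions pinned here, and why:

- **Common start range.** Both window lengths use template starts
  i = 1 … N−m. Every (m+1)-match is then an m-match, so A ≤ B holds
  structurally and SampEn ≥ 0 whenever defined. The common
  1/((N−m)(N−m−1)) normalizations cancel in the ratio and are never
  materialized.
- **Distance and match rule.** Chebyshev distance, match iff d ≤ r
  (the Richman–Moorman convention). For continuous data the boundary
  choice is measure-zero; it is pinned by the oracle tests.
- **Tolerance.** r = r_factor × SD of the series itself (per-series
  mode; sample SD with the n−1 denominator), defaults r_factor = 0.6,
  m = 3. Per-series scaling makes the statistic invariant to positive
  affine transforms of the signal — the natural choice for voxelwise
  mapping, where signal scale varies across the volume. A fixed absolute
  tolerance is available (`sd_mode="fixed"`). When scans are truncated
  to a common length, the SD is computed on the truncated series — i.e.
  on the series actually entering the match counts.
- **Degenerate inputs.** Constant series (detected by zero peak-to-peak
  range, robust to the ~1e−16 SD a rounded constant can carry), series
  shorter than m+2, and series with zero matches at either window length
  return an UNDEFINED sentinel with a reason code. Downstream ROI means
  skip these voxels and report their counts; substituting any ceiling
  value would bias the ROI means.
- **Preprocessing.** None by default; entropy is computed on the series
  as given. An optional linear-detrend switch exists and defaults off.

### Implementation and verification

Counting walks lag diagonals d = j − i: along a diagonal, the Chebyshev
window test reduces to a run-length count of consecutive within-tolerance
points, giving O(N²) time with a small constant (numba-compiled). The
test suite verifies the counts exactly against an independent pure-Python
exhaustive double loop on hundreds of randomized series, and the value
against two closed forms: SampEn = 0 for strictly periodic series, and
the iid-Gaussian limit −ln(2Φ(r/σ√2) − 1) ≈ 1.113 at r = 0.6 SD (each
extra template point of iid data matches independently with probability
P(|X−Y| ≤ r), X−Y ~ N(0, 2σ²)).

## Aggregation

Entropy maps are summarized over an integer label atlas (0 =
background): per parcel, the mean and sample SD of *defined* voxel
entropies plus the contributing voxel count. A parcel with no defined
voxel yields a missing cell, never 0. The scans × ROIs table orders rows
lexicographically by (subject, condition, scan index) so downstream
matrices are bit-for-bit reproducible, and round-trips through CSV
exactly (`%.17g` write, round-trip float parsing on read).

Class-level scalars (cortical / subcortical / network) are unweighted
means over the ROIs of the class — each ROI counts once, matching the
view of the ROI mean as the analysis unit; voxel-count weighting is
available as an option.

## Group statistics

- **Correlation matrices**: Pearson correlation between ROI columns
  across the scans of one condition. Rows with any missing cell in the
  selected columns are dropped listwise so every entry uses the same
  scan set and the matrix stays positive semidefinite.
- **Paired t-tests**: rest vs task paired by (subject, scan index) —
  the only deterministic pairing the 2×2 scan design admits. Raw and
  Bonferroni-adjusted p-values (min(1, p × family)) are always reported
  together; the family size is the number of simultaneous tests in the
  emitted table (7 for networks, 1 for the whole-brain class contrast)
  and is recorded in the output. All-identical differences make t
  undefined and are reported as a sentinel row, not an exception.
- **Two-factor ANOVA**: classical balanced two-way decomposition with
  interaction (SS_A + SS_B + SS_AB + SS_error = SS_total). The designs
  here are balanced, where Type I/II/III sums of squares coincide;
  unbalanced input is rejected rather than silently re-weighted. A
  zero-variance response reports 0/0 F ratios as missing.
- **ICC(3,1)**: two-way mixed, single-measure, *consistency* intraclass
  correlation, (BMS − EMS)/(BMS + (k−1)EMS) with k = 2 scans, from the
  subjects × scans ANOVA strata. It is insensitive to a fixed shift
  between scans (scan2 = scan1 + c gives ICC = 1).
- **Scan consistency**: per ROI, ICC(3,1) and Pearson r across subjects
  between scan 1 and scan 2, plus a two-tailed paired-t p comparing the
  scan means (labeled as such in the output); at group level, the
  Pearson correlation between the two vectors of ROI means (reported as
  missing when fewer than 3 ROIs are available).

ANOVA and ICC are implemented directly from the classical formulas
(they carry contracts — balanced-design rejection, the consistency
form — that generic fitters do not enforce); the tests cross-check them
against statsmodels' `anova_lm` and pingouin's `intraclass_corr` as
independent references, alongside frozen hand-computed small-sample
values.

## Synthetic cohorts

The generator produces 4D cohorts with the statistical structure the
analysis assumes, using AR(1) regularity as the single complexity knob:
every voxel of a parcel is an independent stationary AR(1) series
x_t = φ·x_{t−1} + ε_t, and the parcel's effective coefficient in a scan
is

```
φ = φ_rest + φ_task_delta·[task] + subject_offset + scan_offset
```

clipped to [0, 0.98] with clip events counted. Higher φ means more
temporal regularity and lower sample entropy (verified monotone over
φ ∈ {0, 0.3, 0.6, 0.9} at the default series length). AR(1) was chosen
over frequency-domain or chaotic-map generators because its entropy
response is smooth, monotone and cheap; since the φ → SampEn mapping has
no simple closed form, recovery tests use a Monte-Carlo reference curve
(`entropy_phi_reference`).

Defaults and rationale (all overridable per cohort):

- **405 time points** per scan (~5 min at TR = 0.72 s), both
  conditions; a long-rest mode generates longer rest scans to exercise
  truncation.
- **Parcel φ values**: networks 0.52–0.58 at rest, graded so the
  frontoparietal network has the highest entropy and somatomotor the
  lowest; subcortical parcels 0.44–0.46, below the cortical 0.55–0.56,
  so subcortical entropy exceeds cortical. Task deltas 0.05–0.10 encode
  uniformly higher entropy at rest with network-dependent magnitude.
- **subject_sd = 0.045** (per-subject φ offset, shared by all of a
  subject's scans): with scan offsets of SD 0.04 this bounds the
  φ-level test-retest ICC at σ_s²/(σ_s²+σ_g²) ≈ 0.56, and SampEn
  estimation noise pulls the parcel-level ICC into the moderate
  0.4–0.6 band that motivates a reliability analysis.
- **shared_scan_sd = 0.04** (per-scan global φ offset, hitting every
  parcel at once): drives the high between-ROI entropy correlations
  across scans (~0.9 group-level consistency in the demo cohort).
- **innovation_sd = 1.0**: arbitrary, since per-series tolerance makes
  SampEn scale-invariant.

Cohorts are bit-for-bit reproducible from (config, seed): the random
stream order (subject offsets, then scan offsets, then innovations in
subject/condition/scan order) is fixed, and batching of the innovation
draws does not alter it.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: hemodynamic response shape and its low-pass
filtering, physiological (cardiac/respiratory) noise, head motion,
spatial autocorrelation of the BOLD field, and non-Gaussian innovation
distributions. Recovery results demonstrate that the pipeline's
inference is calibrated and directionally correct under the assumed
variance-components structure, not that real BOLD data satisfy that
structure.

## Pipeline

Stages (simulate → map → aggregate → stats) communicate through on-disk
artifacts so expensive entropy maps are computed once. Volumes are
written as uncompressed NIfTI-1 (`.nii`) so identical runs produce
identical checksums (gzip embeds a timestamp); entropy maps store NaN
for undefined voxels plus a parallel uint8 reason lattice, and both
round-trip through disk. Each stage writes a JSON report with the seed,
a config hash, undefined-voxel tallies and a SHA-256 inventory of every
produced file. CSV outputs carry full double precision; rounding happens
only in human-readable displays.

## Problem sizes in validation

The test suite and the acceptance script size their simulations to run
comfortably on a single CPU: oracle equivalence on 200 series of length
20–200; the iid limit on 100 series of length 1000; null calibration on
cohorts of 50 subjects with one voxel per parcel (the paired-t operates
on parcel-level means, so single-voxel parcels exercise the identical
code path at minimal cost — 500 cohorts in the test suite, 200 in the
acceptance script); directional recovery on a 12×12×12 grid with 20
subjects and full-size 405-point scans; ICC recovery on
variance-components series of 200 subjects × 100 replicates.

## Known limitations

- Only hard (integer-label) parcellations; no probabilistic atlases or
  surface-based analysis.
- Single-scale sample entropy only (no multiscale, approximate or fuzzy
  variants).
- Balanced designs only in the ANOVA; unbalanced cohorts must be
  analyzed elsewhere.
- ICC(3,1) consistency only; absolute-agreement ICC(2,1) is out of
  scope.
- The O(N²) counting kernel is exact, not an approximation; for series
  much longer than ~10⁴ points a specialized data structure would be
  preferable.
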