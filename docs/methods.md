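# Methods

## Scope and model

`segconcord` evaluates agreement between two binary segmentations of
the same 3D acquisition.  Comparison is strictly voxel-wise on the
masks' native shared grid: two masks are comparable only if their
dimensions match exactly and spacing/affine agree within an absolute
tolerance (default 1e-3 mm).  Nothing is ever resampled — resampling
would silently change voxel tallies, and masks drawn on the same
acquisition should already share a grid.  Multi-label exports are
binarized by the rule "any label > 0 is foreground", treating the
segmented structure as a single ROI.

All four metrics derive from one confusion tally (TP, FP, FN, TN) of
the ordered pair.  The reference mask defines FN; the comparison mask
defines FP; TN is counted over the whole shared grid, i.e. the image
background.  Consequences worth knowing:

- the pairwise AUC, 1 − ½[FP/(FP+TN) + FN/(FN+TP)], depends on the
  field of view through TN.  Enlarging the background monotonically
  inflates AUC toward 1 − ½·FN/(FN+TP).  AUC values are therefore only
  comparable between pairs on similar grids; DSC, 1−FPRm and 1−FNR are
  background-free.
- 1−FPRm = 1 − FP/(TP+FN) can be negative when the comparison mask
  hallucinates more voxels than the whole reference contains.  It is
  clamped at 0 by default (0 = null similitude); the raw value and a
  clamped flag are always preserved.
- 1−FNR is computed as TP/(TP+FN) directly, which is exact in floating
  point (the algebraically equal 1 − FN/(TP+FN) differs in the last
  ulp).
- DSC of two empty masks is an error, not 1.0 — a silent 1.0 would
  hide upstream failures.  An empty comparison mask against a nonempty
  reference scores DSC 0, 1−FNR 0, 1−FPRm 1, AUC 0.5.
- Values are kept at full precision internally; rounding to 3 decimals
  happens only in the reporting layer.

## Cohort summaries

Agreement metrics over a cohort are heavily skewed (a ceiling near 1
with a failure tail), so the location summary is the median with the
IQR as Q3 − Q1 (linear-interpolation quantiles — the convention is
pinned for reproducibility).  Uncertainty is a seeded percentile
bootstrap CI of the median: 2000 resamples, 95% by default.  The
interval is widened, if necessary, to bracket the point estimate, which
matters only for degenerate samples.  With one observation the CI
collapses to the value.

`compare_strata` is a generic linear-model screen, not any particular
ANOVA dialect: the metric is regressed on the categorical factors
(plus optional continuous adjusters such as age and volume) by OLS and
type-II F tests are reported per term.  A constant response across all
cells is reported as F = 0, p = 1 rather than NaN.  It answers "is
there evidence agreement differs by scanner/anatomy", nothing more; no
multiple-testing correction is applied at this screening stage.

Discordance triage flags cases with DSC below a threshold (default
0.8) into four half-open bins [0, 0.2), [0.2, 0.4), [0.4, 0.6),
[0.6, threshold).  In practice the bottom bin is catastrophic failure
(wrong structure, empty output), the top bin boundary variability.

## Stratified splitting

The hold-out split balances the validation set over the cross of four
categorical covariates (vendor, field strength, location, sequence).
The validation size is round(fraction × n).  Each composite stratum
starts at the floor of its proportional share; single-case strata stay
wholly in training (a rare acquisition context should not be more than
proportionally absent from training).  Remaining slots are then
assigned greedily to the stratum whose increment most reduces the total
absolute deviation of per-level marginal counts from proportionality
(largest fractional remainder and stratum name as deterministic
tie-breaks), followed by a swap-refinement pass that moves single slots
between strata while doing so lowers the (max, sum) of marginal
deviations.  Plain largest-remainder reconciliation on composite strata
alone was observed to leave rare levels (e.g. 3 T scanners) up to ~2
cases short of proportionality when their cases sit in singleton
strata; the marginal-aware assignment keeps every level within one case
of its proportional share while still allocating strata-wise.  Within a
stratum, members are drawn uniformly under the seed, so the assignment
is fully deterministic given (records, fraction, covariates, seed).

K-fold partitioning is deliberately simpler: a seeded shuffle into
folds of size ⌈n/k⌉ or ⌊n/k⌋, unstratified — fold-level class balance
is not required for cross-validation error estimation here, and the
hold-out level is where balance guards generalisation claims.

## Phantom simulator

The generator emulates only what the evaluation pipeline is sensitive
to: mask volume scale, boundary-error direction, and the failure-mode
taxonomy.  A ground-truth phantom is the largest connected component of
a thresholded scalar field (an anisotropic ellipsoid distance plus
Gaussian-smoothed noise scaled by `shape_irregularity`); the threshold
is the k-th largest field value with k iterated until the realised
volume is within 10% of target.  Phantoms are convex-ish smooth blobs:
they do not mimic infiltrative margins, bilateral tumors or
slice-anisotropic manual contours, so passing simulator-based tests
shows the *pipeline* is correct, not that any segmentation model works
on real images.

A disagreeing mask is derived by operators applied in a fixed order
(failure-mode override; net dilation/erosion; boundary flips; removal
of a connected patch; satellite blobs), pinned because the composition
is not commutative and seeds must reproduce outputs exactly:

- **boundary flips**: outer-shell voxels switch on with probability
  2·rate·balance, inner-shell voxels switch off with probability
  2·rate·(1−balance), both capped at 1.  `flip_balance` = 0.5 is
  symmetric disagreement; 0.93 (the inter-observer preset) makes it
  false-positive dominated, reproducing the empirical signature of a
  wide-contouring second reader (1−FNR near 1, 1−FPRm distinctly
  lower).  The symmetric rate alone cannot produce that signature,
  which is why the balance knob exists.
- **miss_fraction** removes a connected patch grown from a surface
  voxel, trimmed to exactly round(f·V) voxels, so the resulting DSC has
  the closed form 2(V−r)/(2V−r) — used as an oracle in tests.
- **satellites** are disjoint blobs placed in a ≤10-voxel shell around
  the tumor (adjacent lymph nodes mistaken for tumor); **failure
  modes** produce an empty mask, a disjoint wrong structure (DSC
  exactly 0), or satellites only.

`calibrate_perturbation` bisects one monotone parameter
(`boundary_flip_rate` or `miss_fraction`) until the mean DSC over a
handful of seeds is within ±0.02 of target (the public default);
unreachable targets raise.  Monotonicity holds exactly at fixed seed
because the flip thresholds act on one shared uniform draw.

`simulate_agreement_cohort` calibrates once on a median-volume phantom
(internal tolerance 0.004, so the cohort median centers on the regime
target), then applies the fitted parameters to every case with
per-case lognormal volumes.  Default problem size is a 64³ grid at
1 mm spacing with median tumor volume 15,000 mm³ (σ_log = 0.45, clipped
to grid feasibility) — a scaled-down regime chosen so a 132-case cohort
simulates in seconds while keeping surface/volume ratios in a realistic
band; metadata-only cohorts (`generate_cohort`) default to the
clinical scale instead (volume median 116,518 mm³, IQR 219,084; age
lognormal, median 24.5 months, IQR 54; covariate quotas 54/51/27
Siemens/GE/Philips, 116/16 at 1.5/3 T, 105/27 abdominopelvic/
cervicothoracic, 84/48 T2w/T2w-fat-sat).  Covariate marginals are exact
by largest-remainder quota with independently shuffled columns, so the
joint composition is random but the margins are pinned.

## Time audit

Workflow leverage is summarised on mean per-case times:
100·(1 − mean(alternative)/mean(manual)), for both the fully automatic
workflow (inference time only) and the realistic validate-and-edit
workflow (visual validation plus manual correction time).  The former
is an upper bound on real savings since every automatic mask still
needs human review before use.

## Numerical and degenerate-input conventions

- Every random step flows from an explicit integer seed through
  `numpy.random.default_rng`; no global state.
- Tolerances: grid compatibility 1e-3 mm absolute; phantom volume ±10%;
  calibration ±0.02 (public default) / 0.004 (cohort simulation).
- Erosion that annihilates a mask falls back to the unchanged mask
  rather than producing an empty output (empty outputs are an explicit
  failure mode, not a side effect).
- `kfold_partition` requires 2 ≤ k ≤ n; `stratified_split` requires a
  fraction strictly inside (0, 1); summaries reject empty inputs.

## Known limitations

- Surface-distance metrics (Hausdorff, ASSD) are out of scope; two
  masks can share a DSC yet differ in worst-case boundary distance.
- The pairwise AUC's dependence on the field of view is inherited from
  its definition; it is reported for completeness, not recommended as a
  primary endpoint.
- The perturbation model has no spatial correlation structure beyond
  its shells and patches; real inter-observer disagreement concentrates
  at ambiguous interfaces, which the phantoms do not model.
- `compare_strata` assumes independent cases; repeated scans of one
  patient would need a mixed model, which is not provided.
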