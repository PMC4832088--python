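# Methods

## The analysis

`vbmpattern` implements an anatomical multivariate pattern analysis (MVPA)
for two diagnostic groups observed through voxel-based morphometry (VBM):
each subject contributes a modulated, spatially smoothed gray-matter (GM)
partial-volume map on a common voxel grid (typically 2 mm isotropic MNI
space), and the question is whether the joint pattern of GM values
discriminates the groups, which voxels carry the discrimination, and how
classification certainty relates to behaviour.

### Feature selection

Inside each cross-validation split, the average training-control map is
subtracted from the average training-case map and the resulting difference
image is z-transformed *across voxels*:

    z_v = (diff_v − mean_v(diff)) / sd_v(diff)

with the sample SD (n − 1) over all in-mask voxels; a constant difference
image gives an all-zero z-map. Voxels with |z| ≥ t are selected. The
threshold t defaults to 4.25, the best performer in the classical sweep
{3, 3.5, 4, 4.25, 4.5}. Selection is two-sided because discriminative
regions occur in both directions (case > control and control > case); a
one-sided rule could never return the control-dominant regions. Note this
z is a *spatial* standardization of the difference image, not a per-voxel
test statistic: its null distribution across voxels is approximately
standard normal, so on a pure-noise cohort a threshold of 4.25 over ~3·10^4
voxels selects almost nothing. Analyses on null data therefore use t = 3,
the smallest swept value, which keeps selections non-empty.

A `scope` switch controls whether the z-map is recomputed from the
training subjects of each split (`split`, the default — no test-set
leakage) or fixed once from the full sample (`full`), which some published
workflows appear to have used.

### Classifier and cross-validation

The classifier is a binary soft-margin linear SVM (libsvm via
scikit-learn's `SVC(kernel="linear")`) at the library default C = 1, with
no feature scaling — GM partial volumes share one scale. Cases map to the
positive side of the hyperplane.

Each of `n_iterations` (default 10,000) iterations draws
`n_train_per_group` subjects per group (default min(n₁, n₂) − 1; 21 at the
default 22/27 sizes) without replacement, selects voxels, trains, and
classifies one held-out case and one uniformly drawn held-out control.
Iterations whose selection is empty are recorded as skipped and excluded
from tallies. Per-iteration RNG substreams are derived from the master
seed by iteration counter, so results do not depend on execution order
and are bit-reproducible.

Per subject this yields: `n_tested`, the proportion of correct test
appearances (`prop_correct`), a majority-vote verdict (correct when
prop_correct ≥ 0.5, ties counting as correct), the *mean classification
accuracy* (MCA) — the proportion of appearances agreeing with the
subject's majority label, hence ≥ 0.5 — and a continuous
`severity_score`, the fraction of appearances classified as case, in
[0, 1]. The headline accuracy is the proportion of subjects whose
majority vote is correct.

### Performance metrics

From the majority-vote confusion table: accuracy, sensitivity,
specificity, PPV, NPV, and d′ = Φ⁻¹(hit rate) − Φ⁻¹(false-alarm rate).
Boundary rates of 0 or 1 are clipped to 1/(2n) and 1 − 1/(2n) of the
relevant marginal so d′ stays finite. Display rounding is half-up to
integer percent and d′ to 2 decimals; raw values are always retained.
Predictive values can be extrapolated to a different prevalence from
expected counts (sens·n_cases hits, (1 − spec)·n_controls false alarms) —
the balanced-design PPV is much higher than any realistic-prevalence PPV,
which is the substantive reason to report the extrapolation.

The permutation test shuffles diagnosis labels across subjects (group
sizes preserved) and reruns the *entire* pipeline, including per-split
selection, per permutation; p is the raw proportion of null accuracies ≥
observed, reported as the bound "< 1/N" when that count is 0 (this is the
convention implied by p < 0.001 at 0/1000 and p = 0.07 at 7%). The
per-permutation CV count can be scaled down independently of the observed
fit's.

### Voxel importance

The CV procedure is repeated, but each iteration trains on a random
⌈0.20·k⌉-subset of the k selected voxels (at least one). Each drawn voxel
accumulates `times_drawn` and `times_correct`; by default a
"classification" is one test prediction (two per iteration), with a
per-iteration counting mode behind a flag. The ratio
times_correct/times_drawn expresses a voxel's importance; ratios based on
fewer than `min_selected` (50) draws are suppressed. Ranking sorts by
ratio, ties broken by draw count.

Identifiability caveat: when the planted (or true) discriminative voxels
dominate the selected set and accuracy is at ceiling, every 20% subset
classifies perfectly and the ratio is constant — importance is then
undefined in practice. The contrast is informative exactly when
discriminative voxels are a minority of the selection and accuracy is off
ceiling; the test suite's importance-recovery check therefore uses a
sparse single planted cluster with a permissive (z = 3) threshold.

### Cluster anatomy and associations

A voxelwise score map (the importance ratio, with under-drawn voxels set
to NaN) is thresholded and decomposed into connected components
(26-connectivity default; 6 and 18 available), dropping components below
`min_size` (10) voxels. Volume is n_voxels × |det(3×3 affine block)|
(8 mm³ per voxel on a 2 mm grid). Because importance ratios plateau
inside a region, cluster *peaks* are located on a sharper statistic when
one is supplied — the pipeline uses the full-sample |difference| map —
with ties broken by scan order. The delineation threshold is a percentile
of the scored ratios; the library default keeps the top 1%, while the
packaged study-scale analyses use the 50th percentile, which mirrors a
regime where the reported regions comprise roughly half of the selected
voxels. Direction of effect per cluster is the sign of
mean(case) − mean(control) of subject cluster-mean GM, with a two-sided
Welch t-test (no specific test is canonical here; Welch is the robust
default). Subject "GM in a cluster" is the mean over member voxels, which
is comparable across cluster sizes.

Brain–behaviour associations are plain Pearson correlations (two-sided,
uncorrected — matching how such tables are conventionally reported) of
each region's subject cluster-means against the five behavioural factor
scores and the severity score, plus the correlation between the
classifier's severity score and behavioural severity.

## The synthetic cohort generator

No scans are distributed with the package, so a generator provides the
ground-truth test bed. It emulates the *statistical* structure of VBM
output, not anatomy:

- **Grid**: 32×32×32 voxels at 2 mm isotropic (the analysis resolution of
  a 2 mm MNI grid), small enough for fast simulation with room for
  separated clusters.
- **Template**: one smooth random texture per cohort (Gaussian noise
  smoothed at σ = 2 voxels, scaled to SD 0.08 around a mean GM of 0.5,
  clipped at 0) shared by all subjects.
- **Planted effects**: hard spheres of signed amplitude added to case
  subjects only, scaled per subject by a dose ~ Normal(1, 0.3). The
  default layout mirrors the reported effect structure: two case>control
  spheres (radii 3.3 and 3.5 voxels ≈ 150 and 180 voxels) and one smaller
  control>case sphere (radius 2.5 ≈ 65 voxels). Default amplitude 0.08 GM
  units was set from an analytic estimate of the post-smoothing
  cluster-mean effect (smoothing shrinks i.i.d. noise SD by ≈ 0.19,
  cluster-mean averaging by more), targeting a standardized cluster-mean
  difference comfortably ≥ 1.5; generated cohorts measure |d| ≈ 3.5–4.5.
- **Noise and smoothing**: i.i.d. Gaussian subject noise (SD 0.1 GM
  units) added before smoothing; the whole image is then smoothed with a
  4 mm FWHM Gaussian (σ = FWHM/(2√(2 ln 2)), mm converted to voxels,
  nearest-edge boundary to avoid wrap-around) and clipped at 0, GM being
  non-negative.
- **Phenotypes**: severity = dose for cases, baseline 0 for controls,
  plus Normal(0, 0.2) noise — severity and anatomy share the dose as a
  common cause, as in a severity-graded disorder. The five factor scores
  (spelling, phonology, short-term memory, visual/attentional confusion,
  whole-word reading) are standardized linear functions of cluster-mean
  GM plus unit noise: spelling and phonology load positively on the
  control>case cluster, whole-word reading negatively on a case>control
  cluster, and the remaining two factors are pure noise. The default
  slope 0.33 against unit noise puts the brain–behaviour correlations
  near |r| ≈ 0.3, a realistic magnitude for such tables.
- **Null cohorts**: `clusters=[]` or `effect_scale=0` (bit-identical).

What the generator does *not* emulate: real cortical geometry and
atlas-referenced locations, registration error, scanner/site effects,
non-Gaussian GM distributions, spatially correlated subject noise beyond
the smoothing kernel, and covariates (age, sex, handedness). Passing
tests therefore demonstrate that the machinery is correct and calibrated
— chance-level behaviour on nulls, recovery of known planted structure —
not that any particular real-data accuracy is reproducible.

## Numerical and design choices

- Sample SD (n − 1) in the z-transform; immaterial at 10^4–10^5 voxels
  but fixed for reproducibility.
- Voxel scan order is row-major over (i, j, k) (last axis fastest);
  column order of the subjects×voxels matrix is therefore stable.
- Analysis mask: voxels whose cross-subject mean GM ≥ 0.05 (a stand-in
  for the usual implicit in-brain mask; excludes empty background in both
  synthetic and real maps).
- Ties: prop_correct = 0.5 counts as correctly classified; equal
  importance ratios rank by draw count; equal peak statistics resolve by
  scan order.
- The external-cohort path applies a single full-sample classifier
  (selection on all subjects, one SVM) without refitting; an ensemble
  majority over split-trained classifiers is available as an option.
- Degenerate inputs fail loudly: single-class training sets, empty
  selections at final training, grid/mask mismatches between cohorts.

## Problem sizes in the packaged analyses

The packaged study-scale checks use 1,000 CV iterations (null calibration
across 10 seeds, and signal recovery), 200 permutations at 60 CV
iterations each, 10,000 importance iterations for the sparse-signal
contrast, and 2,000 importance iterations for cluster recovery; unit
tests run on much smaller matrices. These sizes give stable estimates of
each quantity (e.g. the accuracy SE at 1,000 iterations is well below the
effects being detected) while keeping a full run in minutes on one core.
The full-scale defaults (10,000 CV iterations, 100,000 importance
iterations, 1,000 permutations) remain the config defaults.

## Known limitations

- The repeated random-split scheme tests nearly identical training sets
  against each other; subject-level outcomes are highly correlated across
  iterations, so the variance of the headline accuracy is larger than a
  naive binomial count suggests (measured SD ≈ 0.10 over null cohorts of
  49 subjects vs 0.071 binomial).
- Importance ratios are uninformative at ceiling accuracy (see above).
- No covariate adjustment, no kernel SVMs, no hyperparameter search, no
  ROC analysis, no multiple-comparison correction of association tables —
  all deliberate scope limits.
- Prevalence extrapolation assumes sensitivity and specificity transfer
  unchanged to the new population, which real cohort shifts can violate.
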