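# Methods

`mtconj` implements a voxel-wise group analysis of magnetization
transfer ratio (MTR) maps.  This note records the statistical model,
the numerical choices, and what the synthetic validation does and does
not establish.

## MTR and tissue-weighted smoothing

MTR is the percentage of signal lost to off-resonance magnetization
transfer saturation, `MTR = 100 (M0 - MS) / M0`, computed voxel-wise
from an unsaturated image `M0` and a saturated image `MS` (multiple
gradient-echo acquisitions may first be averaged voxel-wise to raise
SNR).  Voxels with `M0` below a floor (`min_m0`) are marked invalid
(NaN plus an explicit mask) rather than clamped; invalid voxels are
excluded from every downstream statistic.

All spatial processing assumes the inputs are already aligned on one
voxel grid; the package refuses grid mismatches and never resamples.

Group comparability of a quantitative map requires restricting signal
to one tissue compartment.  For compartment `t` (a GM or WM probability
map, optionally modulated by a Jacobian determinant `j` of the
normalizing deformation) the smoothed compartment map is

    smooth(mtr * t * j) / smooth(t * j)

with an isotropic Gaussian kernel (default FWHM 4 mm; per-axis sigma
`fwhm / (2 sqrt(2 ln 2))` in voxel units, so anisotropic voxels are
handled).  The division renormalizes the blur so that signal does not
bleed across compartment boundaries; where the smoothed weight falls
below `floor = 0.05` the voxel is marked invalid — clamping instead
would bias group means at boundaries.  Plain smoothing uses the same
normalized-convolution construction with the validity indicator as the
weight, which doubles as boundary handling (no edge darkening from the
zero padding).  Analysis masks threshold the tissue probability at 0.2
(inclusive `>=`, so the documented boundary case is deterministic).

## GLM and contrasts

The group design is cell-means coded (one indicator per group) with
mean-centered nuisance covariates; the 3-level education covariate
enters as two dummy columns.  Fitting is OLS vectorized across voxels;
a voxel enters only if valid for every subject (listwise deletion keeps
the degrees of freedom a single number).  Contrasts are vectors over
design columns, e.g. `control > sMCI` is `(1, -1, 0)`; with two groups
and no covariates the contrast t equals the pooled-variance two-sample
t exactly (asserted to 1e-10 in the tests).

The score regression (`MTR ~ score + covariates`) reports the score
coefficient, its t, and the squared partial correlation of the score
given the covariates — the R^2 that a scatterplot of covariate-adjusted
MTR against the score would show.  Subjects missing the score or a
covariate are dropped listwise.

## TFCE and permutation FWE control

Threshold-free cluster enhancement integrates cluster support over all
cluster-forming thresholds:

    TFCE(p) = sum_{h = dh, 2dh, ...} e_h(p)^E h^H dh

with `e_h(p)` the voxel count of the connected component containing `p`
in `{stat >= h}`.  Defaults are the method's standard recommendation:
`E = 0.5`, `H = 2`, 26-connectivity, `dh = max(stat)/100`.  Negative
values are enhanced separately on the negated map and subtracted
(signed transform).

The transform is computed exactly in one sweep: voxels are processed in
descending statistic order while a union-find structure tracks
suprathreshold components.  Because components only grow and merge as
the threshold drops, every union event closes a node whose size was
constant over its lifetime, so its total contribution has the closed
form `size^E * dh * sum h^H` over its lifetime steps; per-voxel TFCE is
the sum along the merge-tree path.  This is algebraically identical to
labeling components independently at every threshold (the test suite
asserts 1e-9 agreement with that brute-force construction) but runs in
near-linear time, which is what makes permutation inference with
10^4-10^5 transforms feasible.

Family-wise error control: group labels of the two contrasted groups
are randomly re-assigned (nuisance covariates stay with their
subjects — plain relabeling, not Freedman-Lane), the t-map and its TFCE
are recomputed, and the maximum TFCE over the mask is recorded.  The
observed labeling counts as one permutation, so p-values cannot fall
below `1/n_permutations`; when fewer distinct relabelings exist than
requested they are enumerated exactly.  The FWE threshold is the
`1 - alpha` percentile (linear interpolation) of the max-null sample;
inference is one-sided in the contrast direction by default, since the
contrasts of interest are directional.  With the observed value
included and exchangeable under the null, the probability that any
voxel survives is alpha by construction; the suite verifies ~95 % empty
masks over null cohorts within the exact binomial interval.

Conjunction ("effects shared by both patient groups") is the
intersection of two independently FWE-thresholded contrasts — a valid
and conservative reading of a logical AND.  A minimum-statistic variant
(TFCE of the voxel-wise min-t map against its own permutation null) is
provided as an alternative.  Disjunction (group-specific effects) is
the inference on the direct between-subgroup contrast.

## Mahalanobis effect size

Cluster-wise effect size is `D = sqrt(d' S*^-1 d)` over the cluster's
voxels, where `d` is the vector of group mean differences and `S*` a
shrinkage estimate of the pooled covariance, `S* = lam diag(S) +
(1 - lam) S`.  The intensity `lam` is the analytic
variance-of-covariances estimator evaluated on the correlation scale
(standardized residuals), which makes `D` exactly invariant under
per-feature affine rescaling; it is computed through n-by-n Gram
quantities so clusters with many more voxels than subjects are cheap.
`D = 1` means the group centroids are one pooled standard deviation
apart; this anchor is exact in the univariate case because shrinkage
leaves a single variance untouched.

Two finite-sample facts matter for interpretation.  First, the plug-in
`D` is biased upward when the voxel count `p` is not small relative to
the subject count: the inverse-covariance quadratic form carries the
Wishart factor `df / (df - p - 1)` on top of the mean-noise term
`p (1/n_A + 1/n_B)`, so at `p = 30`, `n = 21` per group the estimate
can run at several times the population distance.  Shrinkage tames the
conditioning but not this bias.  Second, as a consequence, the plain
percentile bootstrap badly under-covers (the bootstrap distribution
re-amplifies the bias): measured coverage at `p = 5`, true `D = 2`,
`n = 21/21` was ~75 %.  The package therefore defaults to the *basic*
(reverse-percentile) bootstrap interval `[2 D_hat - q_hi, 2 D_hat -
q_lo]`, clipped at zero, which cancels the bias to first order;
measured coverage under the same conditions is ~97 %, within the
nominal band.  The percentile interval remains available
(`method="percentile"`).  Bootstrap resampling is over subjects within
group — voxels are features, never resampled; degenerate resamples
(zero-variance feature) are skipped, and more than 1 % of them is an
error.

## Classification

Binary classification from masked voxel values uses feature selection
plus shrinkage LDA inside leave-one-out cross-validation.  Features are
ranked by absolute pooled t (`abs_t`) or the correlation-adjusted t
score (`cat_score`, `(R*)^{-1/2} t` with shrunk correlation `R*`),
computed through the n-by-n Gram spectrum so the decorrelation is
`O(n^2 p)`.  The discriminant is `w = S*^{-1} d` with the same
diagonal-target shrinkage covariance; the threshold sits at the
midpoint of the projected class means shifted by the log prior ratio
(priors = training proportions); score ties go to the first class,
deterministically, and are counted.  Selection runs strictly inside
each training fold — the ranking function never receives the held-out
subject, and a metamorphic test corrupts held-out data to verify the
fold's selection is unchanged.  Defaults: `n_features = 200`,
`ranking = cat_score` (both logged in every report).

Performance is balanced accuracy (chance 0.5 under any imbalance) with
a CI from Jeffreys posteriors of the two class-conditional accuracies
combined by the delta method, and an exact p-value against chance from
the binomial mixture of the two class-conditional correct counts.

## Volumetry

A subject's regional volume is the labeled voxel count times the voxel
volume.  Group contrasts fit `volume ~ group + TIV` (TIV mean-centered)
and obtain the one-sided p-value of the group contrast by permuting
group labels (10 000 by default, observed labeling included); percent
difference is referenced to the first-named group's mean.  The
permutation t statistics are computed in closed form from the 3x3
normal equations, so large permutation counts are cheap.

## Synthetic cohorts

The phantom is a WM core (logistic radial falloff) inside a GM shell on
a 24^3 grid of 2 mm voxels by default — deliberately minimal geometry
whose soft boundaries exercise the 0.2 probability mask and the
tissue-weighted smoothing nontrivially.  Baseline MTR plateaus are 45 %
(WM) and 35 % (GM), typical literature magnitudes; only contrasts enter
the inference.  Spherical ROIs (voxel-center-in-sphere, inclusive
boundary) carry planted effects: additive MTR deltas per group
(negative = demyelination) and multiplicative regional volume scales
for atrophy.  The canonical design places a shared posterior WM effect
in both patient groups and a frontal WM effect only in the
multiple-domain group, mirroring the conjunction/disjunction logic the
analysis is built for.

Noise is white Gaussian convolved to a target smoothness (default FWHM
4 mm) and rescaled by the exact kernel L2 norm so the interior
voxel-wise SD equals `sigma` (default 1.5 percentage points — a
mid-range value for smoothed MTR maps; the spatial covariance of real
MTR noise is not well characterized, so smoothness is an explicit
parameter rather than a fixed constant).  Covariates are drawn from
identical distributions in all groups (age N(70, 8), gender
Bernoulli(13/21), a 3-level education categorical, TIV N(1.45e6,
1.3e5) mm^3), emulating a matched design.  Behavioral scores follow
`score = intercept + slope * (subject ROI-mean MTR) + covariate terms +
noise`; note that regressing MTR *on* such a score recovers `1/slope`
attenuated by the score-noise share, so recovery tests plant
`slope = 1/0.13` with small score noise to target a voxel-wise
MTR-per-score-unit slope of 0.13.  Subject-level label volumes for
volumetry draw a per-subject target volume (lognormal, default CV 10 %)
around the scaled ROI volume and jitter the sphere center sub-voxel so
voxel counts vary smoothly.  Everything is a pure function of the specs
and one seed; same seed, same bits.

What passing these simulations does *not* show: the generator has
stationary noise, spherical effects with sharp edges, perfectly matched
covariates, no registration or segmentation error, no scanner drift or
B1 inhomogeneity, and group-homogeneous effects.  Real-data performance
claims (which regions, which accuracies) are outside what this package
can validate; the simulations validate calibration (FWE, CI coverage,
chance-level classification, permutation p uniformity) and recovery of
known planted structure.

## Problem sizes in the shipped checks

The test suite runs reduced-scale versions of the stochastic
calibration checks (e.g. 60 null cohorts x 200 permutations for FWE
calibration, judged against the exact binomial 99 % interval at that
replicate count; 300-replicate CI coverage with 1000 bootstrap
resamples).  `scripts/acceptance.py` runs the fuller FWE calibration
(200 cohorts x 500 permutations).  Defaults inside the package remain
the full-scale analysis values (10 000 permutations, 5000 bootstrap
resamples).

## Known limitations

- Permutation relabeling supports pairwise group contrasts; compound
  contrasts (e.g. controls vs. pooled patients) would need a dedicated
  scheme (the minimum-statistic conjunction covers the common case).
- Freedman-Lane residual permutation is not the default; with strongly
  predictive covariates plain relabeling can be slightly conservative.
- The cluster-wise `D` inherits the p-close-to-n bias discussed above;
  compare clusters of similar size, and lean on the bias-correcting CI
  rather than the point estimate.
- Education is modeled as unordered dummies; an ordinal treatment would
  use one less degree of freedom.
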