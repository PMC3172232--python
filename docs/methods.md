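# Methods

## The decoding problem

A subject receives alternating blocks of baseline temperature (40 s) and
heat stimulation (30 s) in four functional runs sampled at TR = 2 s; two
runs use painful heat, two use hot-but-non-painful heat, seven blocks per
run, so each subject contributes 14 painful and 14 non-painful stimuli.
Each stimulus is turned into one *example*: a voxelwise map of percent
BOLD signal change. A linear SVM trained on the examples of one subject
group is then asked to classify the stimuli of subjects it has never
seen. The scientific claim being exercised is that pain-evoked BOLD
patterns are similar enough across people — in both location and percent
magnitude — for such a cross-subject decoder to work.

## Synthetic data model

Because no scanner data ships with the package, a generator produces
"already preprocessed" cohorts with the study's statistical structure.
Each voxel time series is multiplicative around a constant baseline
intensity (1000 arbitrary units, so percent change is well defined):

    s(v,t) = 1000 · (1 + g · e(v)/100 · r(t) + d(t) + n(v,t))

- `e(v)`: planted percent-signal-change amplitude of the active condition
  at voxel `v`. The default atlas is an ellipsoidal "gray matter" volume
  on a 32×38×32 grid of 4 mm isotropic voxels with an MNI-like centered
  affine, carrying five 8 mm spherical regions emulating a pain network
  (bilateral parietal-operculum-like, left-insula-like and contralateral
  postcentral spheres at 0.5% for painful vs 0.1% for non-painful heat;
  one cingulate-like sphere with the reverse preference). Amplitudes stay
  below 1%, the empirical scale of pain-evoked BOLD change. Five randomly
  placed single-voxel artifacts at 5% give the artifact filter something
  real to remove. Region centers are specified as fractions of the grid
  extent, so reduced desk-scale grids keep the same layout.
- `r(t)`: the stimulus response, a boxcar over `[onset+6 s, onset+30 s)`.
  The 6 s shift matches the extraction window's rise allowance, which
  makes the noiseless pipeline *exactly* self-consistent: with zero noise
  and drift, extraction returns `g·e(v)` to machine precision — the
  anchor for the round-trip tests. A single-gamma convolution
  (`hemodynamic="gamma"`) is available for less idealized dynamics but is
  off by default, since the averaging-window analysis never uses the
  shape of the rise.
- `g`: per-subject gain, lognormal(0, 0.2) — median subject 1.0, ±20%-ish
  between-subject amplitude spread. The study this emulates reports no
  within- vs between-subject variance decomposition, so this is the
  package's own choice of a realistic spread, fixed once in the config.
- `d(t)`: per-run linear drift, default 0.1% peak-to-trough. Conditions
  alternate across runs so drift cannot mimic the class label.
- `n(v,t)`: i.i.d. Gaussian per voxel-frame, default SD 0.5% of baseline.
  Averaging 10 baseline and 12 stimulus frames leaves ≈0.21% of PSC noise
  per voxel per example, so a planted 0.5% effect has per-voxel SNR ≈ 2.4
  and the 95th percentile of |PSC| over clean gray voxels stays far below
  the 3% artifact threshold.

What the generator does **not** emulate: spatial noise correlations,
physiological noise spectra, motion, scanner drift nonlinearity,
susceptibility dropout, or between-subject anatomical variability. A
consequence worth knowing: with ~165 planted signal voxels pooled by the
decoder, the effective SNR is large and held-out accuracy saturates near
100% under default conditions. Passing tests therefore demonstrate that
the machinery recovers planted structure correctly and that the
statistics are calibrated — not that real-data accuracies of ~80% would
be reproduced, which depends on noise structure no desk-scale simulation
fixes.

## Extraction and feature reduction

A frame belongs to a window when its acquisition onset lies in the
half-open interval `[start, end)`; with TR = 2 s the baseline window
`[onset−20, onset)` contains exactly 10 frames and the stimulus window
`[onset+6, onset+30)` exactly 12. Changing TR changes the frame counts,
never the seconds. Zero-baseline voxels yield NaN and are reported;
vectorization refuses NaN inside the feature mask.

Optional Gaussian smoothing (default FWHM 4 mm, σ = FWHM/2.355 converted
to voxels per axis) is applied to the 4D runs before extraction,
mirroring the usual preprocessing order.

The artifact rule is interpreted as: a voxel is excluded if |PSC| > 3% in
**any** training example, absolute value, one shared mask. A per-example
exclusion would change the feature space between examples, which a single
weight vector cannot accommodate; negative artifacts are as implausible
as positive ones. The mask is built from training-group examples only and
then frozen — test and retest cohorts are projected into the training
feature space, and the pipeline asserts that no testing subject ever
enters a training-stage computation.

## The SVM

Training minimizes `½‖W‖² + C·Σᵢ max(0, 1 − yᵢ(W·xᵢ + Z))` with C = 10 on
raw percent-change features (no standardization — C is interpreted on
that scale) and an unregularized bias. The solver is sequential minimal
optimization on the dual with a precomputed linear Gram matrix,
second-order working-set selection and a 1e−8 maximal-KKT-violation
stopping rule; the bias comes from the KKT conditions at free support
vectors (midpoint of the active bounds if none are free). The problem is
convex and the pivoting deterministic, so training is reproducible
bit-for-bit; the `seed` argument exists only for interface uniformity.
On small random instances the trained objective agrees with an
independent SLSQP quadratic program to ~1e−9 relative, and with libsvm
(scikit-learn, test-only dependency) to ~1e−7.

Numerical conventions: a decision value of exactly 0 is classified
non-painful — a pain detector should not report pain without positive
evidence. Distance to the hyperplane is stored both raw (`|Y|`) and
geometric (`|Y|/‖W‖`); for a fixed model the two rank identically, so
confidence thresholding is unaffected by the choice, and the geometric
one is reported. Training refuses single-class input, NaN features and
all-identical example rows; prediction refuses zero-weight models
(distances would be undefined).

## Confidence rejection

For an exclusion fraction `f`, the `⌊f·n⌋` examples with the smallest
geometric distance are dropped, pooled over all test subjects (not per
subject), and metrics recomputed on the remainder. Ties at the threshold
are broken by stable input order (with a logged warning when all
distances tie). Because the emulated analysis re-derived its threshold
per cohort so that 15% was excluded in each, the default mode works at a
fixed fraction and reports the distance cut it induced; a frozen absolute
threshold can instead be re-applied to a new cohort. The "best balance"
at 15% was a judgment call, not a formalized criterion, so the operating
fraction is a parameter and the full curve (with least-squares cubic
summaries, ≥4 defined points required) is always available.

## Permutation significance of voxel weights

Class labels are permuted within subject (preserving each subject's
14/14 class counts, respecting the grouped exchangeability structure; a
pooled-shuffle option exists since the original description is silent on
this), the SVM is retrained per permutation — reusing the Gram matrix,
at solver tolerance 1e−6, which is ample for a null distribution — and
only weight vectors are kept. Per voxel, the true weight is ranked
against its null: the percentile map uses mid-rank scaling to 0–100, and
the signed significance masks use add-one permutation p-values
`p = (1 + #{null ≥ observed})/(n_perm + 1)` (symmetrically for the
negative direction), flagged when `p ≤ α/2`. The add-one form is exactly
valid and nominally calibrated at finite permutation counts: at 200
permutations and two-sided α = 0.02, signal-free cohorts flag 1.99% of
voxels in expectation (a raw "percentile ≥ 99" rule would flag 3/201 per
side, a ~50% excess). No multiple-comparison correction is applied;
maps are voxelwise, descriptive, and mirror directional red/blue
displays (p01 at α = 0.01, p10 at the α = 0.10 display threshold).

A known behavior on strongly separable data: the correctly-labeled
problem has a wide margin, hence *small* minimum-norm weights, while
near-random relabelings are barely separable and force larger-norm
weights. Planted voxels then rank at the top of the percentile map
(ranking AUC 1.0 in the default study) yet may exceed few absolute null
weights, leaving the α-level masks sparse or empty. On noisier, real-data
regimes the true and null weight scales are comparable and the masks
populate; the calibration of the test itself is unaffected.

## ROI classifiers

Each configured ROI is a sphere (default radius 8 mm) whose voxel
membership is center-within-radius; spheres are intersected with the
frozen gray/feature mask before averaging, so artifact voxels never leak
in. One scalar feature per example (the literal mean PSC over the
sphere) feeds a per-ROI SVM trained and tested exactly like the
whole-brain decoder; a voxelwise-within-sphere mode is available where a
region's pattern, not its mean level, is of interest. Default ROI
centers are the synthetic atlas's planted region centers; user
coordinates come from a YAML/JSON config. Bilateral structures are one
sphere per configured coordinate.

## Evaluation statistics

Accuracy, PPV and NPV are percentages per subject; PPV/NPV are *missing*
(not zero) when a subject has no positive/negative predictions, and
missing values are dropped pairwise from group means and tests. The
group test is a two-sided one-sample t against the 50% chance level of
the balanced design (configurable for unbalanced designs), with the
n−1-denominator sample SD; zero-variance inputs report ±∞ (or 0 when the
mean equals chance exactly). Feeding the embedded published per-subject
tables through this arithmetic reproduces the reported group rows —
86.6/90.3/85.4 with t(7) = 9.9 for the test group, 74.6/83.6/74.4 with
t(7) = 5.5 for the retest group, 80.6% pooled — which is the package's
ground-truth check of the evaluation module.

## Problem sizes used in tests and the acceptance script

The default test run and `scripts/acceptance.py` exercise the full
pipeline at reduced spatial grids — 20×24×20 for the main synthetic study
(16 subjects split 8/8 plus 8 retest subjects, 200 permutations),
12×14×12 with 4-subject groups for the 50-replicate rejection sweep and
the 4-cohort null-calibration run — chosen so the whole suite completes
in a few minutes on one CPU while keeping ≥3 000 gray voxels in the
calibration pool and the full 448-example cohort structure intact.
Temporal structure is never reduced: every simulated run has the full
245 frames, 7 blocks and 28 stimuli per subject.

## Known limitations

- The printed feature count of the original whole-brain analysis (65 839
  gray voxels of 18 124 575) depends on its acquisition grid and
  gray-matter mask and is not reproducible on synthetic grids.
- Reported real-data accuracies (86.6% test, 74.6% retest, 91.8% at 15%
  rejection) are reproduced as arithmetic on the published per-subject
  values, not as measurements: the synthetic cohorts are deliberately
  easier than real data (see above).
- Whether the original 3% exclusion was signed or absolute, and whether
  its mask used training data only, is not stated in the source
  description; the package's choices (absolute, training-only, frozen)
  are documented above.
- ROI accuracy tables on synthetic data reflect the planted geometry,
  not the anatomy-dependent published ROI results.
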