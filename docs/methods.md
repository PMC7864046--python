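# Methods

This note documents the models implemented in `harkit`, the defaults
and the reasoning behind them, what the synthetic test bed does and
does not emulate, and the numerical choices a user may want to audit.

## Signal model and preprocessing

Recordings are multichannel time series with per-channel sampling
rates (sEMG typically 2000 Hz, inertial channels 200 Hz), an activity
label track of non-overlapping intervals, and quasi-static calibration
phases: a standing phase (≥ 1 s; 30 s in a typical protocol) and
optionally a lying phase.

Preprocessing defaults:

* sEMG — 4th-order Butterworth band-pass 10–500 Hz, then a 50 ms
  centered moving average.  The smoothed signal is *not* rectified;
  rectification is implicit in the magnitude-type features (MAV, MMAV,
  SMA), which take absolute values.
* Accelerometer — 8th-order Butterworth low-pass at 10 Hz, then
  division by the mean resultant (vector-norm) acceleration over the
  standing phase, so resting magnitude is 1 g regardless of the
  device's scale factor.
* Gyroscope — 8th-order Butterworth low-pass at 30 Hz, then per-axis
  subtraction of the standing mean (static bias removal).  This
  per-axis bias removal also serves as the default static-error
  correction; a hook accepts a user-supplied ellipsoid calibration
  when device-specific correction is available.

All filters run forward–backward (zero phase).  This halves the
effective roll-off order but introduces no group delay, which matters
because windows are cut on a shared clock across modalities.  Windows
default to 1040 ms with 80 % overlap (208 ms step; 2080 sEMG samples,
208 IMU samples per window).  Each window takes the label covering the
majority of its span; exact ties go to the earlier label (the
labelling rule is otherwise arbitrary and this one is deterministic).
Windows overlapping the standing calibration phase, or covered by no
label, are dropped.

## Orientation, calibration and joint angles

Sensor attitude is tracked by a Mahony explicit complementary filter
on unit quaternions: gyroscope integration corrected by the cross
product between the measured and predicted gravity directions, with
proportional gain `Kp = 0.5` (dimensionless) and integral gain
`Ki = 0` by default.  The gains are configurable; 0.5 converges from a
30° tilt error within seconds at 200 Hz while remaining gentle on
accelerometer noise.  Magnetometers are not used — indoor environments
make heading references unreliable — so yaw is unobservable.  This is
harmless for joint angles because every segment frame is re-referenced
to identity at a standing snapshot (the last standing sample), which
absorbs per-sensor heading offsets.  The filter is initialized from
the mean standing accelerometer vector (tilt-only, zero heading).

The sensor-to-segment rotation `R_seg^sen` (columns = segment axes in
sensor coordinates) is identified per segment:

* X (longitudinal, head-ward) — direction of the mean standing
  accelerometer vector.  The implementation uses the gravity-reaction
  convention: a sensor at rest reads +1 g along the world vertical.
  The standing window must be static (norm standard deviation below
  10 % of the mean, configurable), else calibration refuses.
* Lower-back Z (forward) — mean lying accelerometer vector,
  Gram–Schmidt-orthogonalized against X; Y = Z × X.
* Thigh/shank Y (medial, the knee flexion axis) — hinge-constraint
  self-calibration: the axis pair (j1, j2) minimizing
  `Σ_t (‖g1(t) × j1‖ − ‖g2(t) × j2‖)²` over a motion window, where g
  are the two gyroscope streams.  A hinge forces the angular-velocity
  components orthogonal to the axis to agree in magnitude on both
  sides.  The minimization runs as nonlinear least squares on
  spherical coordinates (4 parameters), multi-started from four
  initial axes; the residual sign cannot fix the axis orientation, so
  the sign is normalized deterministically and an optional anatomical
  reference vector (positive dot product with the medial direction)
  resolves it when available.  The axis sign does not affect the
  unsigned joint angle.  Streams with mean gyroscope magnitude below
  0.2 rad/s raise a non-identifiability error.
* The remaining axis comes from the cross product; measured axis pairs
  closer than 15° raise a degenerate-calibration error.

Joint angles compose per sample: `R_seg^ref = R_sen^ref · R_seg^sen`,
relative rotation `R_seg2^seg1 = (R_seg1^ref)ᵀ R_seg2^ref`, and the
angle between the segments' longitudinal axes
`A = arccos(j1ᵀ j2)` in degrees, with j1 the proximal X axis and j2
the distal X axis mapped through the relative rotation.  Knee flexion
uses thigh vs shank; hip flexion uses lower back vs thigh.  The arccos
form is unsigned — flexion and extension are not distinguished — and
bounded to [0°, 180°].

`correct_imu` rotates every accelerometer/gyroscope sample by
`(R_seg^sen)ᵀ`, expressing the data in anatomical axes.  Because
rotation is a static linear map and the filters are linear and
per-axis-identical, correction commutes with preprocessing; features
computed from corrected mount-rotated data reproduce the
identity-mount features to float precision (the mechanism behind any
calibrated-vs-uncalibrated comparison).

## Feature bank

Per channel: MV, SD, VAR, RMS, SKE, KUR, IQR, P2P, MAV, WL, LD,
Energy (mean square), MMAV, Burg AR(4) coefficients, the three largest
one-sided DFT magnitudes (descending, DC excluded), MPF, MDF, F25,
F75, spectral entropy, and — for sEMG and gyroscope — the
threshold-gated counts ZC, SSC, WAMP.  All non-angle channels add the
five sym4 level-4 wavelet band energies (A4, D4, D3, D2, D1, mean
squared coefficient per band, symmetric boundary extension).
Tri-axial units add inter-axis Pearson correlations (CC_xy, CC_xz,
CC_yz), Jerk (accelerometers: half the summed squared successive
differences over the three axes) and SMA.  For the reference inventory
(4 sEMG + 3 ACC + 3 GYR + 2 joint angles) this yields per-channel
counts 33 / 30 / 33 / 25 and totals 132, 285, 309, 50 — 776 features.

Numerical conventions worth noting:

* VAR is the mean-subtracted sample variance (= SD²).  SKE and KUR use
  population moments (`1/(Nσ³) Σ(x−x̄)³`, `1/(Nσ⁴) Σ(x−x̄)⁴` with
  population σ); a constant window returns 0 for both.
* The gates δz, δs, δw default to 1 % of each window's RMS — noise
  thresholds in the sEMG literature are conventionally set relative to
  the noise floor — and are configurable as absolute values.  ZC
  counts sign changes whose amplitude step exceeds δz; WAMP counts
  jumps exceeding δw (an indicator sum, the standard form).
* AR coefficients follow the prediction convention
  `x_k = Σ a_i x_{k−i} + e_k`, estimated by Burg's recursion (stable
  on short windows; a constant window yields zeros).
* Spectral features use the window as-is (no zero padding); quartile
  frequencies are the first bins where cumulative power reaches 1/4,
  1/2, 3/4 of the total.  The log detector clamps |x| at 1e−12 to keep
  zero samples finite.
* Min–max normalization stores per-column (min, max) so held-out folds
  are transformed with training-fold parameters; out-of-range values
  are not clipped, and constant columns map to zero with a flag.

## Separability and resampling

The Fisher Index is computed feature-wise:
`S_b = Σ p_i (m_i − m)²`, `S_w = Σ p_i Var_i` (class priors = observed
frequencies, population variance within class), `FI = S_b / S_w`.
Scatter traces are additive over features, so the summed Fisher Index
(SFI) of a set is the plain sum — SFI is the criterion for comparing
windowing parameters.  Zero within-class scatter with nonzero
between-class scatter yields +inf (ranked first, flagged); ties in the
descending ranking break toward the lower feature index.

Resampling brings every class to `round(√(n_max · n_min))` rows:
classes above the target are undersampled by random sampling with
replacement, redrawn for each of k = 10 ensemble groups; classes below
are oversampled once by ADASYN (k_nn = 5, the cited algorithm's
default) and the same synthetic rows are shared by all groups, so
groups differ only in the undersampled draws.  Classes between the
extremes are compared to the target and moved toward it.  ADASYN
allocates synthetic counts by largest-remainder rounding of the
normalized out-of-class-neighbour densities (uniform fallback when all
densities vanish) and interpolates each synthetic row between a
minority sample and one of its k nearest in-class neighbours; a class
smaller than k_nn + 1 falls back to duplication with a warning.

## GFSFAN

Stage one ranks features by FI and assigns selection probabilities
decreasing arithmetically from P1 = 0.8 (best) to P2 = 0.4 (worst).
Individuals are masks with exactly `Ninit` active bits, initialized by
weighted sampling without replacement with keys `w_i = u_i^{1/SP_i}`.

Fitness evaluates the mask's columns with LDA and Gaussian naive Bayes
under stratified 10-fold cross-validation on each resampled group:
confusion matrices are summed over folds before per-class F-measures
are computed (stable when folds are small), per-class F-measures are
averaged across the two wrappers, then FM_all (class mean) and FM_min
(worst class) are averaged across groups and combined as
`f = exp(FM_all) + α exp(FM_min)` with α = 0.1 — overall performance
dominates, the worst class breaks ties.  Fold assignments are drawn
once per group and shared by all masks, so individuals are compared on
identical splits; evaluations are cached by mask.

Genetic loop (defaults: population 80, 100 generations; the reduced
budget used in the recovery experiments is population 30, 40
generations): tournament selection of size 2; COFAN crossover with
fitness-adaptive probability in [0.4, 0.8]; MOFAN mutation with
adaptive per-bit probability in [0.1, 0.4]; crowding replacement where
an offspring replaces the most-similar member (shared-bit count) of a
random cohort of 4 only if strictly fitter; and single-elite
protection.  The adaptive rule gives the fittest individual the
protective lower bound and below-average individuals the exploratory
upper bound; crossover uses the larger parent fitness, and — the rule
needing a fitness before the child is evaluated — mutation of an
offspring also uses the larger parent fitness.  Both operators
preserve the activation count by construction: COFAN passes shared
active indices to both children and two-point-crosses the equal-length
disjoint remainders as index lists; MOFAN deactivates each active bit
with the mutation probability and activates an equal number of
uniformly chosen inactive bits.  `Ninit = M` collapses the search to a
single point and returns immediately.

Baselines: Relief-F weights (standard multi-class form, k = 10
neighbours, equal weighting within the neighbourhood,
range-normalized distances) gated at w ≤ 0 with greedy
correlation pruning (|r| > 0.9 keeps the highest-weight member), and
sequential forward selection under the same wrapper F-measure with
improvement tolerance 1e−4.  A caveat from our experiments: the w ≤ 0
relevance gate is a coarse screen — on strongly separated data,
irrelevant features acquire a small positive Relief-F bias because
nearest hits are partly selected for agreeing on noise coordinates —
so the gate removes few noise features; the correlation stage and the
weight ranking do the useful work.

## Evaluation

`P_i = n_ii / Σ_j n_ji`, `R_i = n_ii / Σ_j n_ij`,
`FM_i = 2 P_i R_i / (P_i + R_i)`, with zero denominators mapped to 0.
Stratified folds deal shuffled class members round-robin, so every
fold is as class-balanced as the counts allow and training folds
retain all classes whenever each class has at least two members.
Cross-validation is window-level (as is common; subject-level
splitting is a caller decision — pass precomputed folds).  The six
classifiers use fixed hyperparameters: 1-NN; 8-tree random forest;
linear one-vs-rest SVM with C = 1; nearest centroid; LDA with pooled
covariance regularized by 1e−6 of its mean diagonal; Gaussian NB with
1e−9 relative variance smoothing.  Centroid, 1-NN, LDA and NB are
implemented natively (the wrapper loop calls them thousands of times);
random forest and SVM are scikit-learn adapters, seeded.

## Synthetic test bed

* `generate_signals` emits per-class sinusoids (amplitude, frequency,
  Gaussian noise per channel and class) tiled into labelled epochs —
  enough structure for windowed features to separate classes, with a
  closed form at zero noise.  It does not model sEMG physiology
  (motor-unit trains, spectral shape) or impacts.
* `generate_rigid_body` simulates a two-segment hinge (knee-style):
  both segments rotate about a shared joint axis — the proximal
  segment carries a linearly ramping share (peak 0.4) of the flexion
  so the two angular-rate profiles are not proportional, which is
  required for the hinge-axis objective to have a unique minimizer —
  with configurable true mount rotations, gravity-only accelerometers
  (no linear-acceleration term: the calibration under test uses
  quasi-static information, and this isolates it), ideal gyroscopes,
  optional white noise, and exact ground-truth angles computed from
  the rotation matrices.  Soft-tissue artefacts, sensor misalignment
  drift and translation-induced accelerations are out of scope, so
  passing recovery tests bounds algorithmic error, not real-world
  error.
* `generate_feature_table` plants informative Gaussian features.  The
  default class-mean pattern assigns each informative feature one
  adjacent class boundary (cycling through the n_classes − 1
  boundaries, shift = `gap` standard deviations): every informative
  feature either uniquely guards a boundary or sharpens one guarded by
  a colleague, so a good selector is rewarded for recovering all of
  them rather than a minimal spanning subset.  Redundant features copy
  informative ones plus noise at a tenth of the noise scale.

All generators are bit-reproducible under their seed.

## Problem sizes used in the test suite

The suite favours short recordings and reduced GA budgets: hinge
simulations use 5 s standing + 10 s motion at 200 Hz; the recovery
experiment uses 4 × 60 samples, 100 features, population 30, 40
generations, 10 seeds; noisy joint-angle recovery uses 20 seeds at
accelerometer noise 0.05 g and gyroscope noise 0.5°/s.  These sizes
were chosen as the smallest at which the measured quantities are
stable; the defaults in the code reflect full-scale use (30 s standing
phase, population 80, 100 generations, k = 10 resampling groups).

## Known limitations

* Joint angles are unsigned (arccos), so flexion and extension fold
  onto the same trace; signed angles would need a consistent axis
  convention across subjects.
* The hip is modeled by the flexion angle only; no 3-D Euler
  decomposition.
* The Mahony filter assumes the accelerometer direction is gravity;
  sustained linear acceleration biases attitude, mitigated but not
  removed by the low proportional gain.
* ADASYN operates in the full feature space of the table given to it;
  resampling before feature selection (as done here) means synthetic
  rows are interpolated in the 776-dimensional space, where nearest
  neighbours are less meaningful than in the selected subspace.
* The GA at strongly reduced budgets occasionally converges
  prematurely (the recovery experiment measures 8/10 seeds at the
  reduced budget); the full-size defaults are more reliable.
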