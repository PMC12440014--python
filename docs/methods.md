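# Methods

`laminalpha` analyses where, across cortical depth, spontaneous EEG alpha
power couples to the BOLD signal. This note documents the models and
procedures the package implements, the synthetic data it validates them on,
the numerical choices involved, and the limits of what the tests show.

## The analysis chain

### Alpha-power regressors

A source-space EEG trace is band-passed to 8–13 Hz (4th-order Butterworth,
applied forward–backward for zero phase; only the band itself is a scientific
choice, the filter family is the conventional one) and its analytic-signal
magnitude taken as a continuous alpha-power timecourse. Segments of TR/4
duration flagged as noisy are repaired from the mean of clean segments among
their four nearest neighbours when at least two are clean, otherwise from the
run-level clean mean of the same eyes-open/eyes-closed condition.

The repaired series is demeaned over the whole run (the demeaning window is a
documented choice), convolved with a double-gamma haemodynamic response
function — peak delay 6 s, undershoot delay 16 s, both dispersions 3 s
expressed as the standard deviation of the gamma lobe, undershoot ratio 1/6,
unit peak; all config-exposed — and sampled at the temporal midpoint of each
fMRI volume (TR 3.8 s, 68 volumes per run; onset sampling is available behind
a flag). Three regressors result: the alpha regressor, a 0/1 eyes-closed
boxcar, and the alpha regressor orthogonalised against the boxcar plus an
intercept (removing the mean task effect and leaving volume-to-volume alpha
variability). A paired t-test over block cycles compares eyes-closed to
eyes-open mean power.

### Voxelwise GLM

Each regressor of interest enters an ordinary-least-squares model together
with six motion nuisance regressors and an intercept. t statistics map to z
by matching the exact t tail probability to the standard normal quantile,
which stays calibrated at the low df of a 68-volume run. Because alpha and
BOLD anticorrelate, the negative contrast is carried forward: voxels with
z < −2.3 are grouped by 26-connectivity and a cluster is retained when its
size exceeds the 95th percentile of the maximum null cluster size under a
sign-flipping permutation scheme (nuisance-only fit plus sign-flipped
residual volumes, refit per permutation). The permutation null replaces
Gaussian-random-field theory deliberately: it is assumption-light and its
false-positive rate is itself testable. Runs combine by inverse-variance
fixed effects. Nearest-neighbour upsampling (e.g. factor 4 toward the depth-
modelling grid) preserves the value multiset and rescales the affine.

### Equivolume depths and columns

The grey-matter ribbon is labelled CSF=1, WM=2, GM=3. Per GM voxel, distances
to the WM and CSF boundary surfaces are estimated as the average of two
standard lattice estimators — the unsigned distance transform to the nearest
boundary voxel centre minus half a voxel, and the signed transform (outside
minus inside), whose zero crossing sits on the interface. Their biases have
opposite sign on curved boundaries, so the average tracks the true surface
distance to well under half a voxel on the annulus oracle.

The equidistant fraction a = d_wm/(d_wm + d_csf) is reweighted by local
curvature so that equal depth bins hold equal tissue volume: with the
curvature s of the mid-surface level set (divergence of the normalised
gradient of d_wm − d_csf; both the level set and the divergence smoothed
with sigma = 3 voxels because the second-derivative estimate is lattice-noisy
while true curvature varies slowly), the local inner radius is
rho1 = 1/s − d_wm and the equivolume fraction

    f = a (2 rho1 + a T) / (2 rho1 + T),      T = d_wm + d_csf,

the equal-area shell rule of an annulus; a mirrored rule handles curvature
centred on the CSF side and |s| ~ 0 falls back to equidistant spacing. Bins
1–6 run from WM-adjacent (deep) to CSF-adjacent (superficial); that
orientation is a convention chosen so the deveining recursion runs naturally
from deep to superficial. Depth modelling is performed on an in-plane
upsampled grid (factor 4) so that each bin is several voxels thick — at the
acquisition grid, lattice quantisation alone spreads per-bin counts by ~30%
even for analytically exact fractions.

Columns grow from mid-depth seeds (|f − 0.5| within half a bin) picked by
farthest-point sampling under the within-ribbon geodesic (26-connected graph)
distance, from a seeded random start; each GM voxel joins its geodesically
nearest seed, ties to the lowest seed index. A column is included when any of
its voxels at any depth is cluster-significant, and within included columns
voxels are retained when |beta| exceeds 5% of the maximum |beta| over all
included columns.

### Deveining by spatial deconvolution

Gradient-echo BOLD at depth i mixes the local signal with signal drained
from all deeper depths through ascending venules. The forward model is
triangular accumulation with per-column non-negative weights v:

    m_1 = b_1,    m_i = b_i + v_i * sum_{j<i} b_j      (i = 2..6)

and deveining is its exact inverse, peeling from the deepest depth. The
weights come from the amplitude of low-frequency fluctuations (ALFF) — per
voxel, the square root of the mean within-period variance of the demeaned
signal over all eyes-closed periods — as a venous blood-volume surrogate:
v_i = lambda * mean-ALFF(depth i) / mean over depths, so the weights average
exactly lambda (default 0.25, physiological range 0.2–0.3). ALFF stays in
signal units; lambda absorbs scale. The correction is computed on the
column's depth-mean vector and applied additively to every voxel of that
depth, preserving within-depth spatial variance (voxel-level peeling is
ill-posed when depth occupancy is uneven). Columns with no voxels at depth 1
are anchored at their deepest populated depth and flagged.

A sensitivity worth knowing: after range normalisation, the deveined
profile's sensitivity to lambda at depth i is approximately
delta-lambda · s_i · sum_{j<i} b_j / range, with s_i the normalised ALFF
shape. Lambda-insensitivity of the normalised shape therefore holds when the
accumulated deep signal is small relative to the profile range — the
noise-free robustness fixture uses a superficial-dominated truth profile and
uniform ALFF, squarely in that regime, where the predicted and measured
deviation across lambda in {0.2, 0.25, 0.3} is ~0.015. With a deep-heavy
truth and strong drainage the normalised shape does depend on lambda under
this model.

### Vein proximity

Veins are dark in mean gradient-echo EPI. An unsharp mask (image minus its
2 mm-FWHM Gaussian-smoothed copy) is thresholded at a percentile of the
within-ROI difference (default 5th; the tail direction — dark veins, lower
tail — is a documented choice), giving a vein mask; four 6-connected
dilations minus the vein mask give the surrounding-vein ring (~0.7 mm at
0.175 mm voxels). Per included column, the first-order-polynomial slope of
the depth profile is computed before and after deveining; columns are ranked
by the absolute slope change and split into lower 25% / middle 50% / upper
25% (boundaries at round(n/4) ranks; ties resolved by rank then column id).
The per-class percentage of retained voxels falling in the ring quantifies
vein proximity; the denominator is retained voxels (whether the original
analysis used all active or retained voxels is not determinable, so the
choice is documented here). The upper-25% columns can be excluded before
profile re-estimation. Class differences across subjects are tested with the
one-way repeated-measures ANOVA below.

### Profiles and statistics

Depth profiles average beta over negatively responding retained voxels of
included columns, either pooled across columns ("global mean") or per column
then averaged with equal column weight ("column profile mean"); the negative
selection is redone on uncorrected and deveined maps separately because
deveining can flip signs. Profiles are divided by their (max − min) across
populated depths — sign and shape preserved; a shift-then-scale variant sits
behind a flag — then combined across ROIs weighted by column count, and
across subjects with equal weight (group SEM is across subjects). Depths left
empty cause listwise exclusion of the subject from the ANOVA.

Repeated-measures ANOVAs are computed from the standard marginal-mean
sums-of-squares decomposition; each within-subject effect is tested against
its own subject-by-effect interaction. Post-hoc paired t-tests are two-sided
with Bonferroni adjustment (family defaults to the number of pairs; when
three GLM types are interrogated separately the per-GLM level is 0.05/3 ≈
0.017). No sphericity correction is applied — a known limitation.

## The synthetic study

The generator exists to give every stage a known ground truth.

**Geometry.** A full annulus (inner radius 10, outer 16 voxels, 0.8 mm
iso, 4 slices) of GM between WM (inside) and CSF (outside): curved enough
that equivolume ≠ equidistant, yet with closed-form equal-area boundaries
sqrt(r1² + (k/6)(r2² − r1²)) as an analytic oracle. 16 columns (~2 mm scale).

**Signals.** One global alpha-power series per subject — baseline ×
(1 + 0.5 · eyes-closed) plus an AR(1) fluctuation (stationary SD 0.1, AR
coefficient 0.999 at 500 Hz; AR(1) is a stand-in, not an inference about
real alpha dynamics). The neural drive per depth is the unit-SD alpha
regressor scaled by −amplitude (default 4) times a depth-weight profile:
"n" (1, 1, 0.5, 0.5, 1, 1), flat, or superficial. For regressor-type
dissociation the drive instead has a boxcar-locked component (flat weights,
amplitude 5) and a spontaneous component (alpha orthogonalised to the
boxcar, "n" weights). Drives pass per column through the forward drainage
model; perivascular voxels additionally receive their column's superficial
measured signal times a gain (default 1 where veins are simulated).

**Noise.** Per-voxel low-frequency fluctuations (three seeded sinusoids in
0.01–0.08 Hz, random phases, exact per-depth SD (0.3, 0.8, 18, 18.2, 18.6,
19) — a stylised venous-volume profile, negligible in the deepest laminae
and quasi-saturated from mid-depth outward) plus white noise (SD 0.6) on a
baseline of 100, with vein voxels darkened by 40%. The low-frequency
mixture is residualised against the regressor/motion subspace before
scaling: it then carries the ALFF depth structure without adding variance
along the regressors, so fluctuation amplitude and response estimation
decouple. Real physiological noise does leak into response estimates; this
construction deliberately isolates the drainage mechanism instead. Motion
nuisance traces are smooth AR(1) series, likewise residualised against the
paradigm subspace (they never enter the BOLD; this keeps the 68-volume
design well conditioned rather than randomly collinear).

**Drainage self-consistency.** The generator's drainage weights are the
fixed point of v = lambda_sim · ALFF(bold(v))/mean: veins drain in
proportion to their realised fluctuation amplitude, which is exactly the
relation the estimator assumes. Consequently an analysis at the same lambda
recovers the generator's weights to machine precision and profile recovery
is unbiased; explicit weights can be supplied instead for algebraic
round-trip tests. This is a modelling idealisation: on real data the
ALFF-drainage relation holds only approximately, and recovery would degrade
accordingly.

**What the tests show — and do not.** Passing recovery tests show the chain
is internally consistent and statistically calibrated under the generator's
assumptions: global drive, drainage exactly triangular with ALFF-proportional
weights, noise orthogonal to the design, perfect tissue labels, no motion in
the data. They do not show robustness to segmentation error, residual motion,
physiological noise correlated with the task, non-triangular vascular
pooling, or inter-subject anatomical variability.

## Problem sizes and numerical choices

Study-scale experiments use 8 subjects per group and 10–20 seeded replicate
groups (the acceptance script uses 10); the cluster permutation null uses
100–200 permutations (fewer than 100 flags a warning in the result); the
null-calibration experiment uses 10,000 voxels and 200 null runs. These
sizes make every experiment reproducible on a single CPU in minutes while
keeping the Monte-Carlo error of the reported fractions around or below the
margins being tested.

Degenerate inputs are handled explicitly: all-noisy segment runs, constant
regressors, rank-deficient designs, empty ROIs/masks/column sets, zero
profile range, all-zero ALFF (deveining becomes the identity), columns
missing depth 1 (anchored, flagged), and missing ANOVA cells all raise or
flag rather than silently imputing. F ratios whose numerator and denominator
are both zero to rounding precision are reported as 0 (p = 1). One global
seed expands through tagged `SeedSequence` streams into per-stage,
per-subject substreams, so any stage can be rerun in isolation bit-identically.
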