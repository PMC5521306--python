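# Methods

## The model

`dotppi` estimates task-dependent effective connectivity in volumetric
oxyhemoglobin (ΔHbO) recordings with a generalized psychophysiological
interaction (gPPI) model.  At each voxel j,

    y_j(t) = X_TDR(t) β_TDR + y_s(t) β_TIC + X_TDC(t) β_TDC + e_j(t)

with per-condition task-response regressors `X_TDR` (stimulus streams
convolved with the canonical HRF), the seed signal `y_s` (main effect
of seed / task-independent connectivity), and per-condition interaction
regressors `X_TDC` whose coefficients carry the effective-connectivity
claims.  A significant β_TDC for a condition means the seed's influence
on that voxel changes while that condition's stimuli are on.

Two TDC constructions are provided.  The hemodynamic-level form is the
elementwise product of the mean-centered seed signal with a TDR column.
The neural-level form deconvolves the HRF from the seed signal
(ridge-regularized Toeplitz inversion; the penalty is picked by
generalized cross-validation unless given), mean-centers the estimate,
gates it by the binary stimulus vector (1 during each 2-s trial), and
reconvolves with the same kernel.  Using the same kernel on both sides
makes the construction robust to kernel misspecification: whatever the
deconvolution gets wrong, the reconvolution largely undoes.

Mean-centering the physiological signal before forming products is
essential: uncentered products are nearly collinear with the TDR
columns (the fit aborts via a condition-number guard with a hint to
center).

## Canonical HRF

A double-gamma impulse response `h(t) = g1(t−d) − c·g2(t−d)` with onset
delay d = 2 s.  The gamma shapes are fixed (6 and 12); the two scales
and the undershoot weight c are solved numerically (three equations:
stationarity at the 7-s peak and the 17-s undershoot, and undershoot
depth = 0.2 of the peak).  The sampled kernel is peak-normalized,
exactly zero before 2 s, and decays below |h| = 0.01 by 32 s.  The
undershoot-depth ratio 0.2 is a modeling choice exposed as a parameter;
only the three temporal landmarks are treated as fixed characteristics
of the auditory ΔHbO response.

## Preprocessing

Per run: (1) superficial-signal regression — each voxel is replaced by
its residual against [intercept, scalp trace]; the nuisance trace is
supplied externally (the generator's ground-truth trace, or any
measured shallow-layer average), since reconstructing it from optode
geometry is out of scope; (2) zero-phase order-3 Butterworth bandpass,
0.02–0.5 Hz; (3) decimation to 1 Hz.  The 0.5-Hz band edge sits exactly
at the 1-Hz Nyquist frequency; filtering happens at the 10-Hz
acquisition rate before decimation and a warning is logged for the
marginal band.  Field-of-view masks keep voxels whose flat-field
sensitivity is within two orders of magnitude of the maximum; group
masks are the voxelwise AND over subjects.

## Statistics

Per-run GLMs are ordinary least squares; runs are pooled with
inverse-variance fixed effects, and t statistics are mapped to z by
two-tailed CDF matching, capped at |z| = 38.  Group maps are one-sample
random effects over subject maps.  Cluster correction is nonparametric:
sign-flip permutations of the subject maps generate the null
distribution of the maximum 26-connected cluster extent above the
forming threshold z = Φ⁻¹(1−0.001) ≈ 3.09; clusters survive at
permutation p ≤ 0.05.  No parametric fallback exists — calling the
thresholding without permutations is an error.  Autocorrelation
modeling (prewhitening) is deliberately out of scope; subject-level z
values are therefore mildly overdispersed when the noise has 1/f
structure, which the group-level random-effects t absorbs (it only
uses between-subject variability).

Seeds: ten canonical speech-network locations; subject-specific seeds
relocate a canonical seed to the nearest significant (z > 3.09) local
activation peak when it lies within 18 mm — a couple of voxels beyond
the array's ~14-mm point spread — and otherwise keep the canonical
location, so every subject has a seed.  Two radii are deliberately
distinct and separately configurable: seed definition spheres are 3 mm
(6-mm diameter), signal extraction averages voxels within 6 mm.  On
grids coarser than ~7 mm the extraction radius is enlarged to half the
voxel diagonal so the sphere always contains a voxel center.

Connectivity matrices average z values within 9-mm axis-aligned cubes
at the ten canonical ROI centers (sub-threshold voxels of a thresholded
map count as zero — exclusion would leave empty cubes undefined); one
gPPI fit per seed yields one row, so the matrix is not symmetric.  The
deconvolution comparison is a paired two-sided t-test per seed-ROI pair
at Bonferroni-corrected alpha (0.05/10 = 0.005).  The scrambled-signal
control reassigns seed signals between runs by a uniformly drawn
derangement (no run keeps its own signal), reruns the gPPI, and
compares pooled seed-to-ROI values with a two-sample chi-square on
common equal-width bins (48 by default; bins with expected counts
below 5 are merged with neighbors; dof = usable bins − 1).  Self-pairs
(a seed with its own ROI) are excluded from the pooled comparison: a
seed trivially predicts its own region whatever the coupling structure,
so including them would make the control reject even for an uncoupled
brain.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the study conditions end to end: four runs of
30 easy + 30 complex + 10 noise 2-s stimuli in seeded pseudorandom
order (constant across subjects for a fixed seed), ISIs uniform on a
0.1-s grid over 2–10 s, button events 1.5 s after sentence onsets with
seeded sides; ten spherical regions at the canonical coordinates on a
3-mm grid (50×58×44 voxels; the voxel lattice is centered on a fixed
world box so coarser desk-scale grids cover the same anatomy); neural
activity per region = evoked boxcar responses + coupling inputs from
earlier-listed regions (task-independent gain a plus condition-gated
modulation b) + intrinsic noise; hemodynamics by convolution with the
canonical HRF, painted with a Gaussian 14-mm-FWHM spatial falloff (the
array's point spread); plus a shared superficial 1/f trace
(amplitude 3), voxelwise 1/f noise (amplitude 2) and white noise
(amplitude 1), all at the 10-Hz frame rate.  Signal units are
arbitrary: the pipeline is scale-invariant and no physical ΔHbO scale
is asserted.

Two generative choices matter and are deliberate:

* Couplings act on the source's *full* activity (evoked plus intrinsic
  noise), computed in the declared region order so the graph stays
  acyclic.  This is what makes interaction coefficients identifiable at
  all: with deterministic sources, a gated source is exactly
  proportional to the task boxcar and the interaction column collapses
  into the TDR column.
* Intrinsic neural noise has a 1-s correlation time (Gaussian-smoothed
  white noise; the parameter recovers white noise at 0).  Ongoing
  cortical activity is slow relative to the 10-Hz frame rate, and only
  fluctuations below the hemodynamic pass band are observable through
  the HRF — white-at-10-Hz intrinsic noise would put ~90% of the
  interaction carrier above what a 1-Hz hemodynamic recording can
  represent.

Amplitudes (evoked gain 1, intrinsic noise 2, superficial 3, 1/f 2,
white 1) were fixed once to give subject-level evoked z-scores in the
range optical speech studies report, with endogenous fluctuations
exceeding single-trial evoked amplitudes as in cortex.

Features of real recordings the generator does not emulate: optode
geometry and photon transport, two-wavelength spectroscopy, motion
artifacts, cardiac/respiratory peaks, head-size variability, spatially
correlated instrument noise, and between-subject anatomical
variability (all subjects share the region layout).  Passing tests
therefore validate the *analysis machinery* — regression geometry,
model identifiability, calibration of the statistics, directionality
of the comparisons — not robustness to those unmodeled artifacts.

## Recovery battery and problem sizes

The end-to-end acceptance battery simulates ten replicates of
ten-subject groups, each subject with three runs on a 12-mm grid, with
a single ground-truth modulation (complex-sentence gating of the
anterior superior temporal → right ventral prefrontal connection,
b = 0.5) on top of six task-independent couplings (a = 0.4); the
zero-coupling control uses twenty three-subject replicates of the same
configuration.  These sizes — coarser grid, three of the four protocol
runs — are the package's desk-scale choices for a single-CPU run; the
statistics scale to the full grid unchanged.  The battery scores:

* recovery — the group random-effects map of the complex-condition
  neural-level TDC should attain its global maximum inside the target
  region's image (within the 14-mm point-spread footprint, plus half a
  voxel diagonal; region centers are ≥ 35 mm apart so the assignment is
  unambiguous);
* the neural-level vs hemodynamic-level comparison at the true pair
  (paired over the 100 pooled subjects, Bonferroni threshold 0.005);
* the scrambled-signal control with true couplings (chi-square
  rejection, scrambled values centered near zero) and with zero
  couplings (false-rejection rate).

A scaling analysis of the recovery readout is worth recording.  At
b = 0.5, the information about the interaction is carried by the
seed's endogenous fluctuations, and the dominant noise at target
voxels is the target's *own* endogenous activity — the same process
at the same amplitude.  Per-run subject-level TDC z at the true pair
is therefore capped near 2 regardless of instrument-noise settings
(both signal and noise scale together), giving per-subject z ≈ 3–4
over three runs with between-subject spread ≈ 2–3.  A ten-subject
random-effects t at the target then sits near 5–7 while the maximum of
thousands of null t(9) voxels sits near 5–6, so the global-maximum
criterion succeeds in most but not all replicates (~70–80%); making it
near-certain would need either several more runs per subject than the
protocol contains or a stronger modulation than b = 0.5.  The battery
reports the observed hit count honestly rather than redefining the
readout.

## Numerical choices

* GCV grid for the deconvolution penalty: 40 log-spaced values over
  eight decades below the largest squared singular value; the Toeplitz
  operator's SVD is cached per (kernel, length).
* Convolution is causal, zero-padded before run start, truncated to
  the input length.
* t→z conversion caps at |z| = 38 (the double-precision limit of the
  normal quantile); zero-variance random-effects voxels with nonzero
  mean hit the cap, zero-mean ones map to 0.
* Cluster labelling uses 26-connectivity.
* Ties in nearest-peak seed relocation resolve to the higher z, then
  lexicographic voxel order; the 18-mm limit is inclusive.
* Run-length mismatches in the scrambled control truncate all runs
  (and their event lists) to the shortest run.
* Float32 is used for simulated volumes and their filtering (relative
  error ~1e-4, far below the simulation noise floor); fitting is done
  in float64.

## Known limitations

* No prewhitening: subject-level z maps are overdispersed under 1/f
  noise and should be read as descriptive; group inference is
  random-effects and unaffected.
* The chi-square control pools seed-to-ROI values that share underlying
  data, so its false-rejection rate can sit slightly above nominal.
* Subject-specific seeds depend on peak detection in individually noisy
  maps; at desk-scale group sizes most seeds fall back to canonical
  locations.
* The generator's couplings are feed-forward (acyclic) by construction;
  reciprocal or lagged influences are out of scope, as are ΔHbR
  analyses and dynamic causal models.
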