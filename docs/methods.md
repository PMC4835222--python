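# Methods

This note records the models, numerical choices and limitations behind
`vertisource`, in the order the pipeline applies them.

## Scope and shape

The package is a library plus narrative example scripts; there is no
command-line entry point because cohorts are generated in-process and the
pipeline is one function call. All file formats used are standard (EDF,
CSV, TSV, JSON).

## Preprocessing

Recordings are resampled to 128 Hz (polyphase FIR with mean-padding, so a
constant signal is preserved exactly), band-passed 2–44 Hz with a 4th-order
Butterworth applied forward–backward (zero phase — a deliberate choice so
that later phase-based measures, LPS and nesting, see no filter-induced phase
distortion), and re-referenced to the common average. Artifact screening is
automated thresholding on non-overlapping 1-s windows: a window dies when any
channel's peak-to-peak amplitude exceeds 100 µV or its mean channel variance
exceeds 4× the median window variance. Surviving windows are merged into
segments; 1 s is trimmed at each segment end to remove filter transients,
and a subject with under 60 s of clean data is flagged (not dropped — the
caller decides). Thresholds are configuration keys. This is an automated
stand-in for visual artifact inspection; it catches amplitude events, not
stereotyped physiological artifacts (no ICA).

## Head model

A three-shell concentric-sphere conductor (brain/skull/scalp radii 80/85/92
mm; conductivities 0.33/0.0042/0.33 S/m) replaces a boundary-element model.
The scalp potential of an interior dipole is the classical Legendre series;
for each harmonic order the radial boundary-value problem across the shells
is solved exactly by a 5×5 linear system, and the series is truncated
adaptively once `n·f^(n-1) < 1e-7` for the worst eccentricity `f = b/R_scalp`
(well beyond the 1e-6 relative-term target; ~80–130 terms at default
geometry). The implementation reproduces the closed-form homogeneous-sphere
solution to better than 0.1% when the shells are collapsed, and gain columns
are average-reference projected. The spherical model preserves every
algorithmic property downstream (linearity, localization, reference
handling); it does not model real skull geometry, so absolute topographies
differ from a BEM — acceptable because no claim here depends on anatomical
accuracy.

The source space is a cubic lattice (default 11 mm) clipped to a radial
"gray matter" band of 0.55–0.95 brain radii (~1100 voxels), a coarse
surrogate for a cortical template. The 12 ROIs are spheres (default radius
18 mm) around approximate head-centered centroids for the left/right
vestibular cortex (BA43), precuneus (BA7), frontal eye field (BA8),
intraparietal sulcus (BA40), orbitofrontal cortex (BA11) and dorsal anterior
cingulate (BA24). A voxel inside several spheres goes to the nearest
center; exact midline ties are assigned to neither so mirrored ROIs stay
mirror-symmetric. These spheres are declared approximations of Brodmann
parcels, not reconstructions.

## Inverse solution

The operator is the Tikhonov minimum-norm inverse `T = K^T (K K^T + αH)^+`
with `α = alpha_frac · trace(K K^T)/n_sensors` (default `alpha_frac` 0.05;
the pseudo-inverse lives on the range of the centering matrix `H`). sLORETA
standardization divides each voxel's current estimate by its resolution
block `R_vv = [T K]_vv`; the standardized power of a noiseless single-dipole
field is maximal at the true voxel for any α (a Cauchy–Schwarz-type
projection argument), which the acceptance suite verifies empirically at
100% of the default grid. Voxel "activity" means this standardized power
throughout; ROI current time series are likewise whitened per voxel by
`R_vv^{-1/2}` before the unweighted voxel mean, so no voxel dominates by
depth bias.

Cross-spectra use 2-s Hann windows at 50% overlap pooled across clean
segments (windows never straddle segment boundaries only in the sense that
segments are concatenated after edge-trimming; the residual discontinuities
are one per segment and negligible at these window counts). A band is the
closed interval of FFT bin centers matching its printed edges; inter-band
gaps (e.g. 3.5–4 Hz) belong to no band. Per band, the voxel value is the
real trace of the standardized 3×3 source cross-spectrum. ROI log power is
the log of the ROI's fraction of total map power, with zero fractions
clipped at 1e-12 to keep group statistics finite.

## Lagged phase synchronization

Fourier coefficients of 2-s Hann windows are normalized to unit modulus
(phase-only; the amplitude-weighted variant is available behind a flag),
averaged into the coherency `ρ_f`, and scored `Im(ρ_f)²/(1 − Re(ρ_f)²)`,
clipped to [0, 1]; the degenerate limit `|Re ρ| → 1` scores 0, making
identical series score exactly zero. The band value is the unweighted bin
mean; at least 8 windows are required. For ROI series the scalar reduction
is the first principal component across the three current components with
the sign fixed by the largest-|loading| rule (deterministic). Whether to
use a multivariate coherency over the full 3-component currents instead was
an open design point; the scalar route was chosen for interpretability and
symmetry, and is recorded in output metadata by construction (it is the only
route the pipeline uses).

## Alpha–gamma nesting

The statistic follows five literal steps: band-pass the 3-component ROI
series at 8–12 and 30–44 Hz; per band, keep the first principal component
(largest-loading sign rule); Hilbert envelope of the gamma component; trim
1-s filter margins; Pearson correlation of the alpha *waveform* with the
gamma envelope. Correlating the signed waveform (rather than alpha phase or
envelope) measures waveform-to-envelope locking — it differs from mainstream
phase–amplitude-coupling indices (Tort MI, Canolty MVL) but is implemented
literally as specified; it is zero in expectation for unmodulated gamma and
grows monotonically with the planted modulation index.

Two consequences are documented rather than hidden. First, an amplitude
modulation at alpha rate throws sidebands ±8–12 Hz around the gamma carrier,
partly outside a 30–44 Hz filter, so even a noise-free construction cannot
reach r = 1 at the default bands; tests therefore check the statistic
against the refiltered construction's own correlation, and use a wider
carrier band when asserting near-perfect recovery. Second, the sign of the
first principal component is a convention: within one subject it is
bit-reproducible, but across subjects it is not physiologically comparable,
so the pipeline's behavioral correlation uses nesting *strength* |r| (both
signed r and |r| are reported per subject).

## Statistics

Group contrasts are voxelwise unpaired t statistics with a max-|t|
permutation null (group labels shuffled; default 5000 permutations, the
corrected p is `(1 + exceedances)/(1 + n_perm)`), i.e. familywise error
control by the maximum statistic. Correlation maps permute the behavioral
vector with max-|r| correction; corrections are applied to both contrasts
and correlation maps. ROI analysis is a per-ROI one-way ANOVA (two groups;
F with (1, n−2) df) on log power — one F per ROI per band, which is the
per-ROI reading of a "one-way MANOVA" label; an optional permutation p is
available. All tests are two-sided. Permutations are fully vectorized and
reproducible from the mandatory seed.

## Synthetic cohorts

Each subject is 13 dipole sources (12 ROI centroids + one posterior-midline
source in the posterior-cingulate/precuneus area) projected through the
spherical lead field with white sensor noise at 10 dB SNR, scaled to ~8 µV
RMS (plausible for band-limited, average-referenced resting EEG — and
compatible with the 100 µV rejection threshold, so clean synthetic data
survive screening). Backgrounds are spectrally shaped 1/f noise;
oscillations are band-pass-filtered noise, not sinusoids, so estimators face
realistic bandwidth. Defaults mirror the emulated study design: 23 patients
+ 23 controls, 5-minute recordings at 500 Hz.

Planted effects and their rationale:

* Patients' posterior source carries an alpha2 (10–12 Hz) peak raised by
  1.0 log-unit. The other sources' alpha peaks sit in alpha1 (8–10 Hz) so
  the alpha2 contrast is spatially identifiable through an inverse with
  19-channel resolution.
* All 12 ROI sources share a gamma-band driver mixed in with per-source
  lags of 8–52 ms at strength 0.6 (controls) vs 0.25 (patients) —
  hypoconnectivity with genuinely lagged, hence LPS-visible, structure.
* The left-FEF source carries per-subject phase–amplitude modulation, index
  drawn uniform on (0.1, 0.9); its gamma carrier is given the same variance
  as the alpha peak so the modulation survives inverse leakage from the 11
  other gamma sources. VAS intensity is drawn as a linear-plus-noise
  function of the standardized modulation index calibrated to r = 0.5 in
  expectation; discomfort, DHI and HADS use the emulated study's sample
  moments and inter-score correlations, clipped/rounded to instrument
  ranges. Controls receive near-floor symptom scores.
* Source orientations are a fixed pseudo-random function of location,
  shared across subjects — a cohort shares anatomy, so a region projects
  to the scalp consistently. Per-subject random orientations would make
  voxel power and recovered component signs incomparable across subjects,
  which no amount of data could undo.

What the generator does *not* emulate: real skull conductivity geometry,
stereotyped artifacts (blinks, EMG), non-stationarity, heterogeneous
per-subject anatomy, or correlated sensor noise. Passing tests therefore
demonstrate algorithmic correctness and recoverability under the stated
model, not clinical validity on hospital EEG.

## Problem sizes in tests and the acceptance script

The unit and acceptance suites run at sizes chosen to keep the full suite
fast while preserving every property under test: a 16-mm grid (~380 voxels,
ROI radius 20 mm) for inverse-based tests, 120-s cohort recordings at the
design rate of 500 Hz for the 12 vs 12 planted-effect reproduction (20
seeds, 800 permutations), 500 permutations and 200-voxel maps over 100 null
cohorts for calibration, and the full default ~1100-voxel grid for the
zero-localization check. `scripts/acceptance.py` repeats these computations
(8 cohort seeds) and writes the measured quantities as JSON.

## Known limitations

* The ROI spheres and centroid table are editable approximations; results
  depend on them only through voxel membership.
* Concatenating clean segments introduces one discontinuity per boundary
  into the window pool.
* The nesting statistic's literal definition caps its dynamic range (see
  above); values near 0.2 at maximal planted modulation are expected, and
  group inferences use its monotonicity, not its absolute scale.
* With 19 sensors, source leakage is substantial; absolute LPS values in
  source space are small, and only contrasts between conditions are
  interpreted.
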