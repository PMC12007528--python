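# Methods

`dianasim` is a desk-scale digital twin of a single-slice DIANA (Direct
Imaging of Neuronal Activity) fMRI experiment: a loop-swapped spoiled-GRE
(SPGRE) acquisition played against a synchronized millisecond-scale visual
paradigm, together with the offline reconstruction and trial-averaged
statistics used to look for candidate responses.  Everything a claim rests on
— dummy-pulse planning, drift behaviour, timing arithmetic, temporal SNR,
detectability — is computable here on synthetic data with known ground truth.

## Bloch engine

Under ideal spoiling the longitudinal magnetization obeys, per excitation,

    Mz <- 1 + (Mz cos(alpha) - 1) E1,      E1 = exp(-TR/T1),

with fixed point `Mss = (1 - E1)/(1 - E1 cos(alpha))` (Ernst equilibrium) and
geometric contraction factor `E1 cos(alpha)`.  Dummy-pulse planning iterates
this recursion from a fully relaxed spin system and reports the first
pre-pulse index whose relative deviation from `Mss` falls below `rel_tol`.

Numerical conventions:

- Transient curves report **pre-pulse** Mz; index 0 is the fully relaxed
  state, so the count equals the number of dummy excitations to play before
  the first steady-state readout.
- `rel_tol` defaults to 0.01 (1% of `Mss`) and is always an explicit, logged
  parameter: the published dummy counts are stated without their convergence
  criterion, and the choice changes the counts materially.
- The default T1 grid is 1000–4500 ms in 500 ms steps, spanning white
  matter, gray matter and CSF at 7 T.  At TR = 5 ms, FA = 4°, 1% tolerance
  this yields counts from 523 (T1 = 1000 ms) to 1519 (T1 = 4500 ms); for
  tissue-like T1 up to ~4300 ms the counts stay at or below ~1480.
- A closed-form cross-check is used in the tests: the approach is
  exponential with effective rate `1/T1* = 1/T1 - ln(cos alpha)/TR`, so the
  count equals `ceil(-T1* ln(rel_tol·Mss/(1-Mss))/TR)` within rounding.

The full RF-spoiled ensemble (isochromats with a uniform 2π intravoxel
gradient-spoiler phase spread per TR, quadratic RF phase cycling
`phi_n = inc·n(n-1)/2`, default increment 50°, 500 isochromats) exists to
verify that the ideal-spoiling shortcut is adequate at 4° flip — its steady
state agrees with `sin(alpha)·Mss·exp(-TE/T2*)` to well under 5% — and is
not on the default planning path.

## Digital phantom

A 2D integer label map with per-compartment `(T1, T2*, pd)`; the per-voxel
baseline is the steady-state SPGRE signal `pd·sin(alpha)·Mss·exp(-TE/T2*)`.
Two deterministic presets:

- `brain_slice`: concentric WM core / GM ring / CSF rim (7 T-like values:
  WM 1200/26 ms, GM 2000/28 ms, CSF 4300/60 ms).  ROIs: `target_v1`, a
  posterior medial GM wedge standing in for calcarine cortex; `control_gm`,
  anterior GM with the voxel count matched exactly to the target (equated
  statistical power); `control_wm`.  Geometry scales with matrix size
  (>= 16) so the same preset serves protocol-size (96/192) and scaled-down
  runs.
- `tubes`: three disks with distinct T1/T2* (MnCl2-doped stability
  phantom) for the drift experiments.

Signal model per sample (multiplicative, matching how results are reported
in percent change):

- **Response**: a phenomenological boxcar (or half-sine) multiplying active
  voxels by `1 + amplitude_pct/100` for trial phase in
  `[onset, onset+duration)`.  Defaults: onset 75 ms, duration 150 ms,
  amplitude 0.05% — the candidate-signal regime of the study; the
  biophysical origin of any DIANA contrast is not modelled.
- **Drift**: global linear multiplicative factor
  `1 + rate/100·t/60` at absolute time `t`; absolute time is continuous
  across dummy periods, runs and scans so inter-run steps come out right.
- **Noise**: spatially uniform white thermal noise whose standard deviation
  is a percent of the mean object baseline, plus optional global
  physiological sinusoids (defaults 0.3 Hz and 1.0 Hz at 0.05% — labelled
  conveniences, not measured spectra; the study reports no physiological
  spectrum for this acquisition, so these exist for property tests only).
  All draws derive from per-(run, trial) seeded streams; identical configs
  and seeds give bit-identical data.
- **Motion**: per-trial 2D rigid transforms, explicit or a seeded Gaussian
  random walk.

What the generator does *not* emulate — 3D anatomy and through-plane motion,
inflow/saturation physics, coil sensitivities, EPI distortion, structured
(non-sinusoidal) physiological noise — bounds what green tests mean: they
validate the statistical chain under its own assumptions, not the in-vivo
detectability of any real DIANA effect.

## Acquisition

Schedules are explicit event lists `(phase_line, time_point, trial_index,
absolute_time)` with one event per TR:

- **DIANA (loop-swapped)**: trial k samples one line at all
  M = (stim+ISI)/TR time points; N trials fill a run in N·M·TR seconds.
  The k-space centre is revisited every N·M·TR, so drift appears as an
  inter-run step.
- **SPGRE (conventional)**: image i acquires all N lines consecutively; the
  centre is passed every N·TR and drift appears as an image-to-image ramp.

Sampling evaluates the instantaneous phantom image at each event's absolute
time and trial phase, applies the trial's rigid motion, takes the 2D DFT and
stores the scheduled row.  This ignores intra-readout dynamics (readout <<
TR at 650–810 Hz/pixel bandwidth) and uses a square, fully sampled k-space.
Phase-encode ordering is sequential by default (the protocol's ordering is
unstated); centric ordering is available because centre-line timing drives
drift sensitivity.  Stimulus onset is anchored to the first imaging
excitation (trial phase 0), emulating the trigger-synchronized paradigm.
Parallel imaging (the 192-matrix protocol's GRAPPA 2) is deliberately not
simulated; the fully sampled 192 matrix is generated instead.

Presets `paradigm_I` … `paradigm_V` carry the protocol table (stimulus
50/200/100 ms, ISI 550/500/600 ms, 10–11 runs × 3–4 scans, matrix 96 or
192), giving M = 120 or 140, run duration 67.2 s at 96×140×5 ms, and
749.2 s (~12.5 min) for 2000 dummies + 11 runs.

## Reconstruction and motion correction

Per time point: inverse 2D DFT, magnitude; optional 16-bit linear
quantization (off by default — a fidelity stressor, not a correctness
requirement).  Undersampled input raises, never silently zero-fills.

Rigid registration minimizes the sum of squared differences over the image
interior (a 5-pixel border margin is excluded so the zero-filled resampling
edge cannot bias the fit), initialized by subpixel phase correlation and
refined by a Powell search over (dx, dy, theta); resampling is cubic-spline
with zero fill (background is air).  On noise-free phantom images known
transforms up to 2 px / 2° are recovered to ~1e-3 px / 1e-2°, comfortably
inside the 0.1 px / 0.1° contract.  The reference image is the temporal mean
of a designated run (default: the first retained run; which run the original
analysis averaged is unstated).  Estimation failures on degenerate frames
are flagged in the motion table and the frame is left uncorrected — never
silently dropped.

## Statistical chain

Per run and voxel, in this exact order: percent signal change relative to
the temporal mean; linear detrend (mean restored); Gaussian temporal
smoothing — "width = 3 time points" is read as a 3-tap kernel, with sigma
0.6 samples chosen so the kernel is effectively supported on 3 taps; ROI
average; then mean ± 95% t-interval across runs (runs are the exchangeable
unit, pooled across subjects for group results).  The first run of each scan
is discarded before analysis, mirroring the residual-transient precaution of
the original protocol.

**Per-trial normalization** is implemented in k-space, per phase line — the
only reading under which "each trial is individually normalized" is
computable, since one trial contributes one line.  Dividing a line by its
raw temporal-mean magnitude would also erase the line's static k-space
amplitude and destroy spatial encoding, so the implemented factor is the
trial mean *relative to the line's across-run mean*: multiplicative drift (a
pure per-trial scale) is removed exactly while the reconstructed image is
preserved; drift-free data are left essentially untouched.  With a single
run the factors are unity — within-run drift in a loop-swapped acquisition
is a static k-y modulation (spatial, not temporal), and the residual
within-trial ramp is removed by detrending.  An image-domain per-run scaling
exists as a comparison mode.

**Response characterization** is descriptive, not inferential: onset is the
first post-stimulus time point opening a contiguous stretch where the
pointwise lower confidence bound exceeds zero, duration is that stretch's
extent, and a stretch must last at least 25 ms (5 samples) to count — with
~140 pointwise 95% intervals per trace, single-point excursions occur in
nearly every null trace and are not treated as detections.  No multiplicity
correction is applied.  The reported amplitude is the peak of the mean
course over the detected stretch, divided by the attenuation that
mean-baselining and detrending impose on a boxcar of the detected extent
(both are linear projections, so the attenuation is a deterministic factor
computable from the detected support alone; for a 150 ms boxcar at 75 ms
onset in a 700 ms trial it is ~0.65).  Without this correction the raw peak
under-reads the injected amplitude by ~35% even at zero noise.

**tSNR and detectability**: per-voxel tSNR is temporal mean over temporal
std (zero-variance voxels flagged, excluded from ROI summaries); the ROI
mean course gains sqrt(V) under spatially independent noise.  The minimum
detectable percent change for a two-sided one-sample test on the
per-time-point ROI mean across runs is

    dmin = (z_{1-alpha/2} + z_power) / (tsnr · sqrt(V · n_runs)) · 100,

an i.i.d. closed form that agrees with a Monte-Carlo power simulation to a
few percent at the tested operating point.

**Fourier localizer** (for BOLD-based slice placement): each voxel's
amplitude spectrum is projected, at the paradigm fundamental and harmonics
up to Nyquist, onto the expected spectrum of the block paradigm (default 5 s
on / 7 s off, 360 volumes at 1 s) convolved with the canonical double-gamma
HRF (standard 6 s peak / 16 s undershoot, ratio 1/6), scaled by the
off-harmonic RMS amplitude.  The detection threshold is calibrated by
seeded white-noise simulation at a 5% false-positive rate; the original
threshold is unstated.

## Simulated study conditions

The acceptance-level simulations run at scaled-down problem sizes chosen as
the package's standard desk-scale conditions: matrix N = 32 with M = 140
(the paradigm-III trial structure), 90 pooled runs (the group pooling of the
three-subject paradigm), thermal noise calibrated analytically so the
per-voxel magnitude tSNR is ~1000 (the calibration accounts for the
sqrt(2) magnitude-noise reduction when k-space is assembled from
independently noisy samples), drift 0.5 %/min, and injected boxcars of
0.02–0.5% at 75 ms onset / 150 ms duration.  Under these conditions the
chain recovers amplitudes with single-digit-percent bias, onsets to the
sample, and control ROIs stay null.

## Known limitations

- Single-slice 2D only; through-plane motion is unrepresentable and
  uncorrectable by construction.
- The response is injected phenomenologically; nothing here speaks to
  whether a neuronal DIANA contrast exists.
- The pointwise-CI response summary is descriptive; its minimum-duration
  rule is a pragmatic specificity device, not a corrected test.
- GRAPPA/parallel imaging, EPI readout physics, eddy currents and coil
  arrays are out of scope.
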