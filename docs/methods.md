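# Methods

`dotstream` implements a real-time processing chain for continuous-wave
fNIRS/DOT: calibration-based baselining, motion-artifact (MA) simulation
and correction by a windowed denoising autoencoder (DAE), causal band-pass
filtering, channel-level hemodynamics via the modified Beer-Lambert law
(MBLL), and volumetric reconstruction through a pre-computed
Tikhonov-regularized inverse of an analytic sensitivity matrix.  This note
records the models, the parameters that matter, the numerical choices, and
what the synthetic validation does and does not establish.

## Signal model and calibration

Raw channel data are light intensities `I(t)` (arbitrary units).  The
working unit is optical density, `OD = -ln(I / I_baseline)`, with the
baseline fixed per channel as the mean intensity over an initial ~30 s
motionless calibration window (a whole-recording baseline is available as
`calibrate(..., baseline="full")` for offline comparisons).  Calibration
also fixes:

- **Channel pruning.** A channel is active iff its mean level is within
  85–125 dB (`10·log10 I`) and its SNR exceeds 17.8 dB.  SNR is
  `mean(I_dB)/std(I_dB)` by default: a screening rule that *keeps* channels
  above a large threshold is only coherent when large means strong and
  stable, which is this convention (the reciprocal `std/mean` form is
  selectable as `convention="std_over_mean"`).  Sample (n−1) standard
  deviations are used throughout.
- **OD statistics.** Per-channel and global (pooled over active channels)
  OD mean and standard deviation, used for the global and local
  standardization of the streaming stage.
- **Geometry.** Source–detector separations, with channels under 15 mm
  labelled short (available for future superficial-signal regression; not
  used further here).
- **Filters.** A causal band-pass as two cascaded Butterworth sections:
  3rd-order low-pass at 0.5 Hz and 5th-order high-pass at 0.05 Hz,
  removing drift/Mayer/respiratory/cardiac structure outside the band.
  Filtering is strictly causal IIR with per-channel state carried across
  calls — streaming one sample at a time is bit-identical to batch
  filtering, which the tests assert.  No zero-phase (forward–backward)
  filtering is used anywhere in the real-time path.

## Motion-artifact model

One artifact is a spike-shaped transient followed by a step-shaped baseline
shift, both with independent random ±1 polarity, parameterized on the
standardized-OD scale in multiples of the resting-state OD standard
deviation:

| parameter | range | units |
|---|---|---|
| spike amplitude | 25.53 – 46.93 | × resting OD std |
| spike duration | 0.40 – 1.05 | s |
| step amplitude | 2.38 – 8.25 | × resting OD std |

Draws are uniform within the ranges.  The spike's extremum sits at the
midpoint of its duration; the shape is a Gaussian truncated at ±3σ mapped
onto the duration (a symmetric triangle is selectable), normalized on the
sample grid so the discrete extremum equals the drawn amplitude exactly.
The step starts where the spike ends and persists to the window end.  The
renderer is linear in both amplitudes, which the property tests exploit.

Training pairs: clean OD channels are z-scored with their whole-recording
mean/std, cut into non-overlapping 100-sample windows (~15 s at 6.67 Hz),
and each window receives exactly one drawn artifact.  Artifacts are
injected per channel independently; a correlated multi-channel mode was
considered and left out of scope as the training protocol treats channels
generically.

## Denoising autoencoder

Encoder: three 1-D convolutions (kernel 3, stride 2, ReLU), widths
1→16→32→64; decoder: three mirrored transposed convolutions, ReLU on the
first two, linear output.  With `same` padding (1) the encoder lengths run
100→50→25→13 and the decoder's output padding (0,1,1) restores exactly 100;
for a general admissible window length the output padding is derived so
output length always equals input length (window length must survive three
stride-2 halvings, i.e. ≥ 8).  Training: MSE against the clean window,
Adam, learning rate 5e-4, 500 epochs by default, batch 64 (batch size and
initialization are implementation choices; weights start Kaiming-uniform,
`U(±1/sqrt(fan_in))`).  The network is implemented directly in NumPy with
manual im2col/col2im backpropagation; training is exactly reproducible
under a fixed seed (single-threaded deterministic kernels), and inference
has no stochastic layers.

On the desk-scale corpus used by the tests and the acceptance script
(~6 400 windows from 6 synthetic subjects), the training loss plateaus by
roughly 300 epochs at ~0.25 (standardized MSE); the runs here therefore use
300 epochs, a problem-size choice recorded in the acceptance script.

## Real-time sliding-window engine

Per incoming sample: OD conversion with the calibration baseline, global
z-scoring with the calibration OD mean/std.  A 15 s window slides in 3 s
steps (in samples: the model's window length, default 100, and
window/5).  On each window completion the window is locally re-scaled by
the *previous corrected window's* scalar mean/std (the calibration
statistics, i.e. (0, 1) on the globally standardized scale, seed the first
window), denoised, and rescaled back; every 3 s segment accumulates the
mean of all window passes covering it — five in steady state — and is
finalized, band-pass filtered and emitted once its last covering window
has been processed.  Earlier provisional values are superseded by the
final averaged value; the engine's flush emits tail segments with however
many passes they received, and samples no window reached pass through
uncorrected (provenance 0), so emitted samples always equal pushed samples
exactly.

Two numerical choices make the engine exactly testable:

- De-standardization is applied in **residual form**,
  `corrected = x + s·(model(v) − v)` with `v = (x − m)/s`, at both the
  local and the global level.  Algebraically identical to
  standardize → denoise → de-standardize, but the pipeline becomes a
  *bit-exact* identity when the denoiser is the identity map, so the
  no-correction control arm is exactly "OD conversion + causal band-pass".
- Segment averaging uses the running-mean recurrence
  `mean += (pass − mean)/count`, which is exact for identical passes and
  matches the "update on every slide" semantics.

A model trained at one sampling rate can serve a stream at another either
in sample units (default: the window is the model's native length
regardless of wall-clock duration) or through an optional linear resampler
that maps each stream window onto the model grid and back
(`init_engine(..., resample=True)`).  Per-stage wall-clock timings are
recorded and reported (`timing_report()`); they are hardware-dependent and
never asserted.

## Hemodynamics and reconstruction

MBLL converts two-wavelength ΔOD to (ΔHbO, ΔHbR) in μM by solving the 2×2
extinction system with path-length correction `DPF·separation`.  The
embedded extinction table holds rounded literature values for 735/850 nm
(molar extinction 450/1102 and 1058/691.3 cm⁻¹M⁻¹ for HbO₂/Hb,
converted to mm⁻¹μM⁻¹ natural-log units) and DPF 6.0 at both wavelengths;
all are configurable, and the forward/inverse pair is exact to float
precision by construction.

The sensitivity (Jacobian) matrix uses the continuous-wave diffusion
approximation in a semi-infinite homogeneous medium (defaults
μa = 0.01 mm⁻¹, μs′ = 1.0 mm⁻¹) with extrapolated-boundary image sources,
and adjoint (Rytov) products
`G(s→v)·G(v→d)/G(s→d) × voxel volume`.  This is an analytic stand-in with
the qualitative structure of mesh-based photon-transport models (banana-
shaped rows peaking between the optodes below the surface, source–detector
symmetry); distances are clamped at half a transport mean free path to
regularize voxels touching an optode.  The inverse problem is pre-solved
with zeroth-order Tikhonov regularization,
`J⁺ = Jᵀ(JJᵀ + λ·α·I)⁻¹`, λ = 0.01 by default with α = max diag(JJᵀ) so λ
is relative to the largest channel self-sensitivity.  Truncation to the
active channels re-derives the inverse from the row-truncated forward
matrix (column-slicing a fixed pseudo-inverse would no longer solve the
reduced problem).  Reconstruction maps per-wavelength Δμa first and
unmixes per voxel afterwards; joint multispectral inversion is out of
scope.  Localization is validated by a forward-crime test (point absorber,
`Δy = JΔx`, centre of mass of the reconstruction within two voxel
pitches) and the λ→0 limit against a direct solve.

## Synthetic data: what it does and does not show

The generator emulates a block-design motor-imagery study at 6.67 Hz:
30 s initial rest (the calibration window), then 12 s task / 15 s rest,
10 repetitions per condition (left/right), with a crude contralateral
response map over the probe.  The clean OD per channel is the sum of a
double-gamma HRF (peak 6 s, undershoot 16 s, ratio 1/6) carried into OD
through the forward MBLL (peak ΔHbO 0.5 μM, ΔHbR −0.17 μM), sinusoidal
cardiac (1.1 Hz, 2e-3 OD), respiration (0.25 Hz, 1e-3), Mayer waves
(0.1 Hz, 8e-4), slow drift (2e-3) and white noise (1e-3); intensity is
`baseline·exp(−OD)` with baselines near 100 dB, so OD conversion is exact
by construction and all intensities are positive.  The 12-module default
probe (one source and one detector per module on a 30 mm grid) yields
two-wavelength channels spanning 10–40 mm separations; desk-scale runs use
a 4-module patch (28 channels).

These amplitudes were fixed once as plausible first-pass magnitudes for
quiet, high-SNR channels.  Two consequences matter when reading the
benchmark numbers:

- The block design's fundamental (~0.019 Hz) lies *below* the 0.05 Hz
  high-pass and cardiac lies *above* the 0.5 Hz low-pass, so the clean
  signal retains only ~1–3e-6 OD² of variance inside the evaluation band —
  far less relative in-band structure than real multi-task recordings
  carry.  Post-filter MSE of the corrected stream lands well below 1e-4
  OD², but the Pearson correlation with the clean reference saturates
  around 0.35–0.40 under these conditions, because the model's
  reconstruction floor is of the same order as the in-band signal itself.
  On data with realistic in-band physiological power (tens of times
  larger), the same error floor would correspond to correlations near the
  published operating point; the synthetic benchmark therefore
  demonstrates artifact-energy removal (MSE, and the paired per-window
  comparison) much more strongly than waveform correlation.
- Sinusoidal physiology with fixed frequencies is easier to encode than
  real quasi-periodic physiology; conversely white noise at 22% of the
  variance is harsher than a good optode contact.  Passing tests establish
  the pipeline's contracts and the denoiser's relative gains on this
  distribution, not absolute performance on any real device.

The benchmark harness enforces subject-wise holdout (it refuses test
subjects seen in training), contaminates every 100-sample window of every
active channel (scaled by that channel's calibration OD std), streams the
contaminated intensities through the engine twice (trained model vs
identity control), and scores both arms against the clean causally
filtered OD, excluding the first 30 s of filter/engine transient.
Metrics are computed per channel (headline) and per channel-window (both
reported); everything is reproducible bit-for-bit under a fixed master
seed.

## Degenerate inputs and tie-breaks

Zero-variance channels cannot be standardized or SNR-scored: they raise a
flagging error (`ZeroVarianceError`) and are pruned.  An empty active set
is an error everywhere (downstream stages need ≥ 1 channel).  A corrected
window with near-zero spread resets the local scale to 1 rather than
dividing by ~0.  Spike durations shorter than one sample interval render
as a single-sample spike at the nearest grid point.  The Tikhonov inverse
refuses an all-zero Jacobian; voxels coincident with an optode are
distance-clamped.  `MASpec` accepts amplitude 0 (an explicit "no
component" sentinel) but otherwise rejects parameters outside the
empirical ranges.

## Known limitations

- The forward model is homogeneous and semi-infinite: no head anatomy, no
  tissue layers, no mesh registration; it is a structural stand-in
  swappable behind `JacobianMatrix`.
- No short-channel regression, no comparison implementations of classical
  MA-correction methods, no live acquisition transport — the replay
  streamer honours the same per-sample contract a live inlet would.
- The DAE's latent sequence rate (fs/8) is below the cardiac band, so
  cardiac content is reproduced imperfectly; this is immaterial after the
  0.5 Hz low-pass but visible in unfiltered outputs.
- Wall-clock latency depends on hardware and is reported, never asserted.
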