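# dotstream

Real-time processing for functional near-infrared spectroscopy (fNIRS) and
diffuse optical tomography (DOT): calibration-based baselining, deep-learning
motion-artifact correction applied through a sliding window, causal band-pass
filtering, channel-level hemodynamics, and fast volumetric image
reconstruction from a pre-computed regularized inverse.

## Who this is for

Brain-computer interface (BCI) and neurofeedback pipelines need cortical
hemodynamics *while the subject moves*: continuous-wave optical recordings
have no absolute baseline, are contaminated by motion artifacts (spikes and
baseline steps from optode-scalp decoupling), and — for DOT — require an
expensive inverse problem per frame.  `dotstream` packages the streaming
counterparts of the usual offline steps so every stage runs sample by
sample with bounded state, and ships a synthetic-data generator so the whole
chain is testable end to end without hardware.

## The processing chain

1. **Calibration** (~30 s rest): per-channel intensity baselines, channel
   pruning (mean level within 85–125 dB and SNR > 17.8 dB), OD statistics,
   source-detector separations, and causal Butterworth band-pass
   coefficients (0.05–0.5 Hz; 5th-order high-pass, 3rd-order low-pass).
2. **OD conversion** per sample: `OD = -ln(I/I_baseline)`.
3. **Motion-artifact correction**: a denoising autoencoder (1-D conv
   encoder 1→16→32→64, kernel 3, stride 2, mirrored transposed-conv
   decoder) maps 100-sample standardized-OD windows to clean windows.  A
   15 s window slides in 3 s steps, so each 3 s segment is denoised five
   times with varying context; the emitted value is the running average of
   the five passes.
4. **Causal filtering** of the corrected OD with persistent per-channel
   filter state (streaming output is bit-identical to batch filtering).
5. **Hemodynamics**: the modified Beer-Lambert law converts two-wavelength
   ΔOD into (ΔHbO, ΔHbR) via the 2×2 extinction system with
   `DPF · separation` path-length correction.
6. **Reconstruction**: channel-to-voxel sensitivities from a continuous-wave
   diffusion model in a semi-infinite medium; the inverse is pre-solved with
   zeroth-order Tikhonov regularization (λ = 0.01, scaled by the largest
   channel self-sensitivity), truncated to the active channels, so a frame
   costs one matrix multiply.

The artifact simulator draws spike+step artifacts with empirical parameter
ranges (spike 25.53–46.93× resting OD std over 0.40–1.05 s, peak at the
duration midpoint; step 2.38–8.25×; random polarities), used both to build
training pairs and to score correction quality on held-out synthetic
subjects.  See `docs/methods.md` for model details and limitations.

## Worked example

```python
import numpy as np
import dotstream as ds
from dotstream.dae import DenoisingAutoencoder, build_training_windows
from dotstream.evaluate import run_benchmark

probe = ds.gen_probe(n_modules=4)                      # 28 channels, 10-40 mm
subjects, split = ds.gen_dataset(n_subjects=9, probe=probe, seed=7)

def od_block(s):
    cal = ds.calibrate(s.recording)
    act = cal.active_channels
    return ds.od_convert(s.recording.intensity[:, act], cal.intensity_mean[act])

rng = np.random.default_rng(7)
windows = build_training_windows(
    [od_block(s) for s in subjects if s.subject_id in split["train"]], rng)
model = DenoisingAutoencoder(epochs=300, seed=7)       # ~6 min on one CPU
model.fit(windows.noisy, windows.clean)

test = [s for s in subjects if s.subject_id in split["test"]]
report = run_benchmark(test, model, split["train"], seed=7)
print(report.summary().to_string(index=False))
```

which prints

```
   condition  mse_mean  mse_std  cc_mean   cc_std  n_channels
contaminated  0.000051 0.000011 0.194203 0.099287          56
         dae  0.000003 0.000001 0.358244 0.052610          56
```

Reading: every 15 s window of the two held-out subjects was hit by one
spike+step artifact per channel; streaming the contaminated data through the
pipeline with the trained denoiser cuts the post-band-pass mean squared
error against the known-clean signal from 5.1e-5 to 3e-6 OD² (a ~16×
artifact-energy reduction) and nearly doubles the mean Pearson correlation.
Correlation saturates well below 1 on this synthetic corpus because the
0.05–0.5 Hz evaluation band retains very little clean variance under the
generator's defaults — `docs/methods.md` quantifies this and what it implies
for real recordings.

A command-line interface wraps the same steps
(`dotstream simulate | calibrate | train | stream | benchmark | reconstruct`).

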