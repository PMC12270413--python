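"""The real-time streaming engine.

Each incoming intensity sample is OD-converted against the calibration
baseline, globally z-scored with the calibration OD statistics, and buffered.
A sliding window (default 15 s, i.e. the denoiser's window length in
samples) advances in 3 s steps; on each completion the window is locally
re-scaled against the previous corrected window's statistics, passed through
the denoiser, and its correction is accumulated per 3 s segment as a running
average.  A segment is finalized once the last window covering it has been
processed (five passes at the default 15 s / 3 s geometry), then mapped back
to OD units, causally band-pass filtered with state carried across segments,
and emitted.

Numerical note: local/global de-standardization is applied in residual form,
``x + s * (denoised - input)``, and the per-segment average uses the running
(Welford) mean recurrence.  Both are algebraically identical to the
textbook standardize/denoise/destandardize/average sequence but make the
pipeline an exact identity when the denoiser is the identity map — a useful
end-to-end invariant.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hemorecon import ExtinctionTable, InverseOperator, mbll, reconstruct_frame
from .preprocess import CalibrationParams, CausalFilter
from .recordings import ProbeLayout, StreamSample

__all__ = [
    "IdentityDenoiser",
    "ResamplingDenoiser",
    "PipelineOutput",
    "StreamingEngine",
    "init_engine",
    "profile",
]


@dataclass
class IdentityDenoiser:
    """No-op denoiser with the window contract of the trained model.

    Substituting it for the DAE turns the engine into the plain
    OD-conversion + band-pass pipeline (bit-for-bit), which serves as the
    no-correction control arm and as an end-to-end oracle in tests.
    """

    window_length: int = 100

    def transform(self, X: np.ndarray) -> np.ndarray:
        return X


class ResamplingDenoiser:
    """Adapts a model trained at one sampling rate to a stream at another.

    Windows of ``stream_length`` samples are linearly resampled to the
    model's native window length, denoised, and the *correction residual* is
    resampled back and added to the original window.
    """

    def __init__(self, model, stream_length: int):
        self.model = model
        self.window_length = stream_length
        self._x_stream = np.linspace(0.0, 1.0, stream_length)
        self._x_model = np.linspace(0.0, 1.0, model.window_length)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        down = np.stack([np.interp(self._x_model, self._x_stream, row) for row in X])
        residual = self.model.transform(down) - down
        up = np.stack([np.interp(self._x_stream, self._x_model, row) for row in residual])
        return X + up


@dataclass
class PipelineOutput:
    """One finalized 3 s segment of the stream (active channels only)."""

    segment_index: int
    sample_start: int
    timestamps: np.ndarray
    od_denoised: np.ndarray          # (n_samples, n_active) OD units
    od_filtered: np.ndarray          # (n_samples, n_active) band-passed OD
    provenance: int                  # number of denoiser passes averaged (0-5)
    dhbo: np.ndarray | None = None   # (n_samples, n_pairs) uM, if enabled
    dhbr: np.ndarray | None = None
    volume: tuple[np.ndarray, np.ndarray] | None = None  # (dHbO, dHbR) voxels


@dataclass
class _SegmentAccumulator:
    mean: np.ndarray
    count: int = 0


class StreamingEngine:
    """Per-sample streaming pipeline around a windowed denoiser.

    Parameters
    ----------
    calibration
        Loaded calibration parameters (baselines, statistics, active list,
        filter coefficients).
    denoiser
        Object with ``window_length`` and ``transform(X) -> X``; typically a
        trained :class:`~dotstream.dae.DenoisingAutoencoder` or
        :class:`IdentityDenoiser`.
    window_s, step_s
        Sliding-window geometry in seconds.  The window length in *samples*
        is the denoiser's ``window_length`` (the model defines its own clock);
        the step is the proportional number of samples and must divide the
        window length so overlap averaging has integer coverage.
    """

    def __init__(
        self,
        calibration: CalibrationParams,
        denoiser,
        window_s: float = 15.0,
        step_s: float = 3.0,
    ):
        self.calibration = calibration
        self.denoiser = denoiser
        self.window_s = window_s
        self.step_s = step_s
        self.window_len = int(denoiser.window_length)
        self.step_len = int(round(self.window_len * step_s / window_s))
        if self.step_len < 1 or self.window_len % self.step_len != 0:
            raise ValueError(
                f"window of {self.window_len} samples is not an integer multiple "
                f"of the {self.step_len}-sample step; overlap averaging needs "
                f"integer coverage"
            )
        self.passes_per_segment = self.window_len // self.step_len
        self.active = list(calibration.active_channels)
        self._baseline = calibration.intensity_mean[self.active]
        self._g_mean = calibration.od_global_mean
        self._g_std = calibration.od_global_std
        if not self._g_std > 0:
            raise ValueError("calibration global OD std must be positive")
        self._filter = calibration.make_filter(len(self.active))
        self._od_rows: list[np.ndarray] = []
        self._z_rows: list[np.ndarray] = []
        self._n = 0
        self._windows_done = 0
        self._segments_emitted = 0
        self._local_mean = 0.0
        self._local_std = 1.0
        self._accum: dict[int, _SegmentAccumulator] = {}
        self._last_timestamp: float | None = None
        self._hemo: tuple[ExtinctionTable, list[tuple[int, int, float]]] | None = None
        self._recon: tuple[InverseOperator, ExtinctionTable] | None = None
        self._timings: dict[str, list[float]] = {
            "od_conversion": [], "standardization": [], "dae": [],
            "averaging": [], "filtering": [],
        }

    # -- optional downstream stages ----------------------------------------

    def enable_hemodynamics(self, probe: ProbeLayout, table: ExtinctionTable) -> None:
        """Emit per-pair (dHbO, dHbR) for SD pairs with both wavelengths active."""
        pairs = []
        active = set(self.active)
        for (s, d), by_wl in probe.sd_pairs().items():
            if len(by_wl) == 2 and all(ch in active for ch in by_wl.values()):
                wl = tuple(sorted(by_wl))
                sep = float(np.linalg.norm(
                    probe.source_positions[s] - probe.detector_positions[d]
                ))
                pairs.append((self.active.index(by_wl[wl[0]]),
                              self.active.index(by_wl[wl[1]]), sep))
        self._hemo = (table, pairs)
        self._hemo_wavelengths = tuple(sorted(probe.wavelengths))

    def enable_reconstruction(self, operator: InverseOperator, table: ExtinctionTable) -> None:
        """Reconstruct one volumetric frame per finalized segment (from the
        segment-mean filtered OD)."""
        for w, chans in operator.active_channels.items():
            if not set(chans).issubset(self.active):
                raise ValueError(
                    f"inverse operator at {w} nm references channels outside the active list"
                )
        self._recon = (operator, table)

    # -- streaming ----------------------------------------------------------

    def push_sample(self, sample: StreamSample) -> list[PipelineOutput]:
        values = np.asarray(sample.values, dtype=float)
        if values.shape[0] != len(self.calibration.intensity_mean):
            raise ValueError(
                f"sample has {values.shape[0]} channels, calibration defines "
                f"{len(self.calibration.intensity_mean)}"
            )
        if self._last_timestamp is not None and sample.timestamp <= self._last_timestamp:
            raise ValueError("stream timestamps must be strictly increasing")
        self._last_timestamp = sample.timestamp

        t0 = time.perf_counter()
        od = -np.log(values[self.active] / self._baseline)
        t1 = time.perf_counter()
        z = (od - self._g_mean) / self._g_std
        t2 = time.perf_counter()
        self._timings["od_conversion"].append(t1 - t0)
        self._timings["standardization"].append(t2 - t1)
        self._od_rows.append(od)
        self._z_rows.append(z)
        self._n += 1

        outputs: list[PipelineOutput] = []
        k = self._windows_done
        if self._n == k * self.step_len + self.window_len:
            self._process_window(k)
            outputs.append(self._finalize_segment(k))
            self._windows_done += 1
        return outputs

    def _process_window(self, k: int) -> None:
        L, S = self.window_len, self.step_len
        start = k * S
        t0 = time.perf_counter()
        win = np.stack(self._z_rows[start: start + L], axis=1)  # (n_active, L)
        m, s = self._local_mean, self._local_std
        v = (win - m) / s
        t1 = time.perf_counter()
        v_out = np.atleast_2d(self.denoiser.transform(v))
        t2 = time.perf_counter()
        corrected = win + s * (v_out - v)  # residual-form local de-standardization
        new_std = float(np.std(corrected, ddof=1))
        self._local_mean = float(np.mean(corrected))
        self._local_std = new_std if new_std > 1e-12 else 1.0
        for seg in range(k, k + self.passes_per_segment):
            block = corrected[:, (seg - k) * S: (seg - k + 1) * S].T  # (S, n_active)
            acc = self._accum.get(seg)
            if acc is None:
                acc = self._accum[seg] = _SegmentAccumulator(mean=np.zeros_like(block))
            acc.count += 1
            acc.mean = acc.mean + (block - acc.mean) / acc.count
        t3 = time.perf_counter()
        self._timings["dae"].append(t2 - t1)
        self._timings["averaging"].append((t1 - t0) + (t3 - t2))

    def _finalize_segment(self, seg: int, end: int | None = None) -> PipelineOutput:
        S = self.step_len
        start = seg * S
        stop = min(start + S, self._n) if end is None else end
        od_block = np.stack(self._od_rows[start: stop], axis=0)
        acc = self._accum.pop(seg, None)
        t0 = time.perf_counter()
        if acc is None:
            od_denoised = od_block
            provenance = 0
        else:
            z_block = np.stack(self._z_rows[start: stop], axis=0)
            # residual-form global de-standardization of the averaged correction
            od_denoised = od_block + self._g_std * (acc.mean[: stop - start] - z_block)
            provenance = acc.count
        t1 = time.perf_counter()
        od_filtered = self._filter.process(od_denoised)
        t2 = time.perf_counter()
        self._timings["averaging"][-1:] = [self._timings["averaging"][-1] + (t1 - t0)] \
            if self._timings["averaging"] else [t1 - t0]
        self._timings["filtering"].append(t2 - t1)
        out = PipelineOutput(
            segment_index=seg,
            sample_start=start,
            timestamps=np.arange(start, stop) / self.calibration.sampling_rate,
            od_denoised=od_denoised,
            od_filtered=od_filtered,
            provenance=provenance,
        )
        if self._hemo is not None:
            table, pairs = self._hemo
            dhbo = np.empty((stop - start, len(pairs)))
            dhbr = np.empty((stop - start, len(pairs)))
            for p, (i1, i2, sep) in enumerate(pairs):
                hbo, hbr = mbll(
                    np.stack([od_filtered[:, i1], od_filtered[:, i2]]),
                    sep, self._hemo_wavelengths, table,
                )
                dhbo[:, p], dhbr[:, p] = hbo, hbr
            out.dhbo, out.dhbr = dhbo, dhbr
        if self._recon is not None:
            operator, table = self._recon
            seg_mean = od_filtered.mean(axis=0)
            dod = {
                w: seg_mean[[self.active.index(c) for c in chans]]
                for w, chans in operator.active_channels.items()
            }
            out.volume = reconstruct_frame(operator, dod, table)
        self._segments_emitted += 1
        return out

    def flush(self) -> list[PipelineOutput]:
        """Emit the stream tail: partially-covered segments keep however many
        passes they received; samples no window reached pass through
        uncorrected (provenance 0)."""
        outputs = []
        seg = self._segments_emitted
        while seg * self.step_len < self._n:
            outputs.append(self._finalize_segment(seg))
            seg += 1
        return outputs

    # -- introspection -------------------------------------------------------

    @property
    def n_samples_seen(self) -> int:
        return self._n

    def timing_report(self) -> pd.DataFrame:
        """Wall-clock per stage (reported only; never asserted)."""
        rows = []
        for stage, vals in self._timings.items():
            total = float(np.sum(vals))
            rows.append(
                {
                    "stage": stage,
                    "calls": len(vals),
                    "total_s": total,
                    "mean_ms": 1e3 * total / len(vals) if vals else 0.0,
                }
            )
        rows.append(
            {
                "stage": "total",
                "calls": self._n,
                "total_s": float(sum(r["total_s"] for r in rows)),
                "mean_ms": 1e3 * sum(r["total_s"] for r in rows) / max(self._n, 1),
            }
        )
        return pd.DataFrame(rows)


def init_engine(
    calibration: CalibrationParams,
    model,
    window_s: float = 15.0,
    step_s: float = 3.0,
    resample: bool = False,
) -> StreamingEngine:
    """Build a streaming engine around a trained denoiser.

    By default the window is the model's native ``window_length`` samples
    regardless of the stream's sampling rate.  With ``resample=True`` the
    window spans ``window_s`` seconds of the stream and each window is
    linearly resampled to the model's length for the denoising pass.
    """
    denoiser = model
    if resample:
        stream_len = int(round(window_s * calibration.sampling_rate))
        if stream_len != model.window_length:
            denoiser = ResamplingDenoiser(model, stream_len)
    return StreamingEngine(calibration, denoiser, window_s=window_s, step_s=step_s)


def profile(engine: StreamingEngine, stream) -> pd.DataFrame:
    """Run a replay stream through the engine and return the per-stage
    timing report (wall clock; informational only)."""
    for sample in stream:
        engine.push_sample(sample)
    engine.flush()
    return engine.timing_report()
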