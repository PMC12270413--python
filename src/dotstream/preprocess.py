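"""Calibration-phase statistics, channel pruning, OD conversion,
standardization and causal band-pass filtering.

A short motionless *calibration* recording (default 30 s) fixes everything a
streaming pipeline needs before the first live sample arrives: per-channel
intensity baselines, optical-density statistics, the active-channel list
(power-range and SNR pruning), source-detector separations with long/short
labels, and the coefficients of the causal Butterworth band-pass
(0.05-0.5 Hz) that removes drift, Mayer waves, respiration and cardiac
pulsation from the corrected OD stream.

SNR convention: the screening rule keeps channels with "SNR > 17.8 dB",
which is meaningful for mean(I_dB)/std(I_dB) (a high value = a strong,
stable channel), the convention of standard fNIRS toolchains.  That is the
default here; the reciprocal std/mean form is available via
``convention="std_over_mean"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .recordings import ProbeLayout, RawRecording, channel_separations

__all__ = [
    "ZeroVarianceError",
    "FilterSpec",
    "CalibrationParams",
    "intensity_to_db",
    "channel_snr",
    "prune_channels",
    "od_convert",
    "standardize",
    "destandardize",
    "design_bandpass",
    "CausalFilter",
    "calibrate",
]

POWER_RANGE_DB = (85.0, 125.0)
SNR_THRESHOLD_DB = 17.8
SHORT_CHANNEL_MM = 15.0


class ZeroVarianceError(ValueError):
    """Raised when a statistic requires nonzero variance (flat channel)."""


def intensity_to_db(intensity: np.ndarray | float) -> np.ndarray | float:
    """Light intensity (arbitrary units) to decibels: ``10 * log10(I)``."""
    intensity = np.asarray(intensity, dtype=float)
    if np.any(intensity <= 0):
        raise ValueError("intensity must be strictly positive for dB conversion")
    out = 10.0 * np.log10(intensity)
    return out if out.ndim else float(out)


def channel_snr(i_db: np.ndarray, convention: str = "mean_over_std") -> float:
    """Signal-to-noise ratio of one channel's dB-scale intensity series.

    Default convention ``mean(I_dB)/std(I_dB)`` (sample std, ddof=1); the
    reciprocal is available as ``"std_over_mean"``.  A zero-variance series
    has no defined SNR and raises :class:`ZeroVarianceError` so callers can
    flag the channel instead of dividing by zero.
    """
    i_db = np.asarray(i_db, dtype=float)
    if i_db.size < 2:
        raise ValueError("need at least 2 samples")
    mean, std = float(np.mean(i_db)), float(np.std(i_db, ddof=1))
    if std == 0.0:
        raise ZeroVarianceError("constant intensity series: SNR undefined")
    if convention == "mean_over_std":
        return mean / std
    if convention == "std_over_mean":
        if mean == 0.0:
            raise ZeroVarianceError("zero-mean series: SNR undefined")
        return std / mean
    raise ValueError(f"unknown SNR convention {convention!r}")


def prune_channels(
    intensity: np.ndarray,
    power_range_db: tuple[float, float] = POWER_RANGE_DB,
    snr_threshold: float = SNR_THRESHOLD_DB,
    convention: str = "mean_over_std",
) -> list[int]:
    """Active-channel screening on a calibration-length intensity block.

    A channel is active iff its mean dB level lies in ``power_range_db`` and
    its SNR exceeds ``snr_threshold``.  Flat (zero-variance) channels are
    pruned.  Returns channel indices in stable (ascending) order; raises if
    every channel is pruned, since downstream stages need at least one.
    """
    intensity = np.asarray(intensity, dtype=float)
    if intensity.ndim != 2:
        raise ValueError("intensity must be (time x channel)")
    lo, hi = power_range_db
    active = []
    for ch in range(intensity.shape[1]):
        col = intensity[:, ch]
        if np.any(col <= 0):
            continue
        i_db = intensity_to_db(col)
        mean_db = float(np.mean(i_db))
        if not (lo <= mean_db <= hi):
            continue
        try:
            snr = channel_snr(i_db, convention)
        except ZeroVarianceError:
            continue
        if snr > snr_threshold:
            active.append(ch)
    if not active:
        raise ValueError("all channels pruned: no usable data")
    return active


def od_convert(intensity: np.ndarray, baseline: np.ndarray | float) -> np.ndarray:
    """Intensity to optical density: ``OD = -ln(I / I_baseline)``."""
    intensity = np.asarray(intensity, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if np.any(intensity <= 0) or np.any(baseline <= 0):
        raise ValueError("intensity and baseline must be strictly positive")
    return -np.log(intensity / baseline)


def standardize(od: np.ndarray, mean: float | np.ndarray, std: float | np.ndarray) -> np.ndarray:
    """Z-score: ``(OD - mean) / std``; exact inverse is :func:`destandardize`."""
    std = np.asarray(std, dtype=float)
    if np.any(std <= 0):
        raise ValueError("std must be positive")
    return (np.asarray(od, dtype=float) - mean) / std


def destandardize(z: np.ndarray, mean: float | np.ndarray, std: float | np.ndarray) -> np.ndarray:
    return np.asarray(z, dtype=float) * std + mean


@dataclass(frozen=True)
class FilterSpec:
    """Causal Butterworth band-pass as two cascaded sections:
    3rd-order low-pass at 0.5 Hz and 5th-order high-pass at 0.05 Hz."""

    sampling_rate: float
    lowpass_cutoff: float = 0.5
    lowpass_order: int = 3
    highpass_cutoff: float = 0.05
    highpass_order: int = 5

    def __post_init__(self) -> None:
        nyq = self.sampling_rate / 2.0
        if not (0 < self.highpass_cutoff < self.lowpass_cutoff < nyq):
            raise ValueError(
                f"need 0 < {self.highpass_cutoff} < {self.lowpass_cutoff} < Nyquist ({nyq})"
            )


@dataclass
class BandpassCoefficients:
    """Numerator/denominator pairs of the two cascaded IIR sections."""

    b_lp: np.ndarray
    a_lp: np.ndarray
    b_hp: np.ndarray
    a_hp: np.ndarray

    def is_stable(self) -> bool:
        return all(
            np.all(np.abs(np.roots(a)) < 1.0) for a in (self.a_lp, self.a_hp) if len(a) > 1
        )

    def frequency_response(self, freqs: np.ndarray, fs: float) -> np.ndarray:
        w = 2 * np.pi * np.asarray(freqs) / fs
        _, h_lp = signal.freqz(self.b_lp, self.a_lp, worN=w)
        _, h_hp = signal.freqz(self.b_hp, self.a_hp, worN=w)
        return h_lp * h_hp


def design_bandpass(spec: FilterSpec) -> BandpassCoefficients:
    """Digital Butterworth sections at the stated orders and cutoffs."""
    nyq = spec.sampling_rate / 2.0
    b_lp, a_lp = signal.butter(spec.lowpass_order, spec.lowpass_cutoff / nyq, "lowpass")
    b_hp, a_hp = signal.butter(spec.highpass_order, spec.highpass_cutoff / nyq, "highpass")
    coeffs = BandpassCoefficients(b_lp=b_lp, a_lp=a_lp, b_hp=b_hp, a_hp=a_hp)
    if not coeffs.is_stable():
        raise ValueError("unstable filter design (cutoff too close to Nyquist?)")
    return coeffs


class CausalFilter:
    """Streaming causal band-pass with persistent per-channel IIR state.

    Feeding samples chunk by chunk produces bit-for-bit the same output as a
    single batch call on the concatenated input (the delay registers are
    carried across calls).  State starts at zero (filter at rest).
    """

    def __init__(self, coeffs: BandpassCoefficients, n_channels: int):
        self.coeffs = coeffs
        self.n_channels = n_channels
        self._zi_lp = np.zeros((max(len(coeffs.a_lp), len(coeffs.b_lp)) - 1, n_channels))
        self._zi_hp = np.zeros((max(len(coeffs.a_hp), len(coeffs.b_hp)) - 1, n_channels))

    def process(self, samples: np.ndarray) -> np.ndarray:
        """Filter a ``(n_samples, n_channels)`` block, updating state."""
        samples = np.atleast_2d(np.asarray(samples, dtype=float))
        if samples.shape[1] != self.n_channels:
            raise ValueError(
                f"expected {self.n_channels} channels, got {samples.shape[1]}"
            )
        y, self._zi_lp = signal.lfilter(
            self.coeffs.b_lp, self.coeffs.a_lp, samples, axis=0, zi=self._zi_lp
        )
        y, self._zi_hp = signal.lfilter(
            self.coeffs.b_hp, self.coeffs.a_hp, y, axis=0, zi=self._zi_hp
        )
        return y

    def reset(self) -> None:
        self._zi_lp[:] = 0.0
        self._zi_hp[:] = 0.0


@dataclass
class CalibrationParams:
    """Everything the streaming pipeline loads before the first live sample."""

    sampling_rate: float
    intensity_mean: np.ndarray       # per channel (baseline for OD conversion)
    intensity_std: np.ndarray
    od_mean: np.ndarray              # per channel
    od_std: np.ndarray
    od_global_mean: float            # over active channels
    od_global_std: float
    active_channels: list[int]
    separations_mm: np.ndarray
    is_short_channel: np.ndarray     # separation < 15 mm
    filter_spec: FilterSpec = field(repr=False, default=None)  # type: ignore[assignment]
    filter_coeffs: BandpassCoefficients = field(repr=False, default=None)  # type: ignore[assignment]

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "sampling_rate": self.sampling_rate,
            "intensity_mean": self.intensity_mean.tolist(),
            "intensity_std": self.intensity_std.tolist(),
            "od_mean": self.od_mean.tolist(),
            "od_std": self.od_std.tolist(),
            "od_global_mean": self.od_global_mean,
            "od_global_std": self.od_global_std,
            "active_channels": self.active_channels,
            "separations_mm": self.separations_mm.tolist(),
            "is_short_channel": [bool(b) for b in self.is_short_channel],
            "filter_spec": {
                "sampling_rate": self.filter_spec.sampling_rate,
                "lowpass_cutoff": self.filter_spec.lowpass_cutoff,
                "lowpass_order": self.filter_spec.lowpass_order,
                "highpass_cutoff": self.filter_spec.highpass_cutoff,
                "highpass_order": self.filter_spec.highpass_order,
            },
            "filter_coeffs": {
                k: getattr(self.filter_coeffs, k).tolist()
                for k in ("b_lp", "a_lp", "b_hp", "a_hp")
            },
        }
        path.write_text(json.dumps(payload, indent=1))
        return path

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationParams":
        payload = json.loads(Path(path).read_text())
        spec = FilterSpec(**payload["filter_spec"])
        coeffs = BandpassCoefficients(
            **{k: np.array(v) for k, v in payload["filter_coeffs"].items()}
        )
        return cls(
            sampling_rate=payload["sampling_rate"],
            intensity_mean=np.array(payload["intensity_mean"]),
            intensity_std=np.array(payload["intensity_std"]),
            od_mean=np.array(payload["od_mean"]),
            od_std=np.array(payload["od_std"]),
            od_global_mean=payload["od_global_mean"],
            od_global_std=payload["od_global_std"],
            active_channels=list(payload["active_channels"]),
            separations_mm=np.array(payload["separations_mm"]),
            is_short_channel=np.array(payload["is_short_channel"], dtype=bool),
            filter_spec=spec,
            filter_coeffs=coeffs,
        )

    def make_filter(self, n_channels: int | None = None) -> CausalFilter:
        return CausalFilter(self.filter_coeffs, n_channels or len(self.active_channels))


def calibrate(
    recording: RawRecording,
    calibration_s: float = 30.0,
    power_range_db: tuple[float, float] = POWER_RANGE_DB,
    snr_threshold: float = SNR_THRESHOLD_DB,
    filter_spec: FilterSpec | None = None,
    short_channel_mm: float = SHORT_CHANNEL_MM,
    baseline: str = "calibration",
) -> CalibrationParams:
    """Compute calibration statistics from a motionless rest recording.

    Uses the first ``calibration_s`` seconds.  The OD baseline is the mean
    intensity over that window (``baseline="calibration"``); for offline
    comparisons ``baseline="full"`` uses the whole recording's mean instead.
    Global OD statistics pool all samples of the active channels.
    """
    fs = recording.sampling_rate
    n_cal = int(round(calibration_s * fs))
    if recording.n_samples + 1 < n_cal:
        raise ValueError(
            f"recording too short for a {calibration_s:.0f} s calibration "
            f"({recording.duration:.1f} s available)"
        )
    block = recording.intensity[:n_cal]
    if np.any(block <= 0):
        raise ValueError("calibration block contains non-positive intensities")
    if baseline == "calibration":
        i_mean = block.mean(axis=0)
    elif baseline == "full":
        i_mean = recording.intensity.mean(axis=0)
    else:
        raise ValueError(f"unknown baseline mode {baseline!r}")
    i_std = block.std(axis=0, ddof=1)
    od = od_convert(block, i_mean)
    od_mean = od.mean(axis=0)
    od_std = od.std(axis=0, ddof=1)
    active = prune_channels(block, power_range_db, snr_threshold)
    if np.any(od_std[active] <= 0):
        raise ValueError("active channel with zero OD variance during calibration")
    seps = channel_separations(recording.probe)
    spec = filter_spec or FilterSpec(sampling_rate=fs)
    return CalibrationParams(
        sampling_rate=fs,
        intensity_mean=i_mean,
        intensity_std=i_std,
        od_mean=od_mean,
        od_std=od_std,
        od_global_mean=float(od[:, active].mean()),
        od_global_std=float(od[:, active].std(ddof=1)),
        active_channels=active,
        separations_mm=seps,
        is_short_channel=seps < short_channel_mm,
        filter_spec=spec,
        filter_coeffs=design_bandpass(spec),
    )
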