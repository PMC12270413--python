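"""Data model and I/O for probe geometry and multichannel optical recordings.

A continuous-wave fNIRS/DOT measurement is a set of *channels*, each a
(source, detector, wavelength) triple defined on a probe of scalp-mounted
optodes.  This module defines the in-memory containers used throughout the
package, a SNIRF-compatible HDF5 reader/writer, and a replay streamer that
plays a stored recording back sample by sample with the same contract a live
acquisition link would provide.

Conventions: indices are 0-based internally (SNIRF stores them 1-based),
positions are millimetres, time is seconds.
"""

from __future__ import annotations

import time as _time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "ProbeLayout",
    "RawRecording",
    "StreamSample",
    "channel_separations",
    "save_recording",
    "load_recording",
    "replay_stream",
    "channel_table",
]


@dataclass(frozen=True)
class ProbeLayout:
    """Optode geometry and the channel list defined on it.

    Parameters
    ----------
    source_positions, detector_positions
        ``(n, 3)`` arrays of 3D positions in mm.
    channels
        Sequence of ``(source_index, detector_index, wavelength_nm)`` triples,
        0-based.  Channel identity is the full triple; each (source, detector)
        pair may appear once per wavelength.
    wavelengths
        The distinct wavelengths (nm) used by the device.
    """

    source_positions: np.ndarray
    detector_positions: np.ndarray
    channels: tuple[tuple[int, int, float], ...]
    wavelengths: tuple[float, ...]

    def __post_init__(self) -> None:
        sp = np.asarray(self.source_positions, dtype=float).reshape(-1, 3)
        dp = np.asarray(self.detector_positions, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "source_positions", sp)
        object.__setattr__(self, "detector_positions", dp)
        object.__setattr__(
            self, "channels", tuple((int(s), int(d), float(w)) for s, d, w in self.channels)
        )
        object.__setattr__(self, "wavelengths", tuple(float(w) for w in self.wavelengths))
        self._validate()

    def _validate(self) -> None:
        ns, nd = len(self.source_positions), len(self.detector_positions)
        seen: set[tuple[int, int, float]] = set()
        for s, d, w in self.channels:
            if not (0 <= s < ns):
                raise ValueError(f"channel references source {s}, but probe has {ns} sources")
            if not (0 <= d < nd):
                raise ValueError(f"channel references detector {d}, but probe has {nd} detectors")
            if w not in self.wavelengths:
                raise ValueError(f"channel wavelength {w} nm not in probe wavelength list")
            if (s, d, w) in seen:
                raise ValueError(f"duplicate channel (source={s}, detector={d}, wavelength={w})")
            seen.add((s, d, w))
        sep = channel_separations(self, _validate=False)
        if np.any(sep <= 0):
            bad = int(np.argmin(sep))
            raise ValueError(
                f"channel {bad} has non-positive source-detector separation ({sep[bad]:g} mm)"
            )

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    def sd_pairs(self) -> dict[tuple[int, int], dict[float, int]]:
        """Map (source, detector) -> {wavelength: channel index}."""
        pairs: dict[tuple[int, int], dict[float, int]] = {}
        for i, (s, d, w) in enumerate(self.channels):
            pairs.setdefault((s, d), {})[w] = i
        return pairs


def channel_separations(probe: ProbeLayout, *, _validate: bool = True) -> np.ndarray:
    """Euclidean source-detector separation of every channel, in mm."""
    src = probe.source_positions[[c[0] for c in probe.channels]]
    det = probe.detector_positions[[c[1] for c in probe.channels]]
    return np.linalg.norm(src - det, axis=1)


@dataclass
class RawRecording:
    """A multichannel continuous-wave intensity recording.

    ``intensity`` is a ``(n_samples, n_channels)`` array of non-negative light
    intensity in arbitrary units; ``annotations`` is a list of
    ``(time_s, label)`` task markers.
    """

    intensity: np.ndarray
    sampling_rate: float
    probe: ProbeLayout
    annotations: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.ndim != 2:
            raise ValueError("intensity must be a 2-D (time x channel) array")
        if self.intensity.shape[1] != self.probe.n_channels:
            raise ValueError(
                f"intensity has {self.intensity.shape[1]} columns but probe defines "
                f"{self.probe.n_channels} channels"
            )
        if not self.sampling_rate > 0:
            raise ValueError("sampling_rate must be positive")
        dur = self.duration
        self.annotations = [(float(t), str(lab)) for t, lab in self.annotations]
        for t, lab in self.annotations:
            if not (0 <= t <= dur):
                raise ValueError(f"annotation {lab!r} at {t} s outside record of {dur:.3f} s")

    @property
    def n_samples(self) -> int:
        return self.intensity.shape[0]

    @property
    def n_channels(self) -> int:
        return self.intensity.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate


@dataclass(frozen=True)
class StreamSample:
    """One time point of a live (or replayed) acquisition stream."""

    timestamp: float
    values: np.ndarray


# ---------------------------------------------------------------------------
# SNIRF-style container
# ---------------------------------------------------------------------------

_FORMAT_VERSION = "1.0"


def save_recording(rec: RawRecording, path: str | Path) -> Path:
    """Write a recording to a SNIRF-compatible HDF5 container.

    The layout follows the SNIRF specification (``/nirs/data1`` with a
    ``measurementList``, ``/nirs/probe`` with 3-D optode positions, and one
    ``/nirs/stim*`` group per annotation label); optode indices are stored
    1-based as SNIRF requires.
    """
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data=_FORMAT_VERSION)
        nirs = f.create_group("nirs")
        data = nirs.create_group("data1")
        data.create_dataset("dataTimeSeries", data=rec.intensity)
        data.create_dataset("time", data=rec.times)
        wl = list(rec.probe.wavelengths)
        for i, (s, d, w) in enumerate(rec.probe.channels, start=1):
            ml = data.create_group(f"measurementList{i}")
            ml.create_dataset("sourceIndex", data=s + 1)
            ml.create_dataset("detectorIndex", data=d + 1)
            ml.create_dataset("wavelengthIndex", data=wl.index(w) + 1)
            ml.create_dataset("dataType", data=1)  # CW amplitude
            ml.create_dataset("dataTypeIndex", data=1)
        probe = nirs.create_group("probe")
        probe.create_dataset("sourcePos3D", data=rec.probe.source_positions)
        probe.create_dataset("detectorPos3D", data=rec.probe.detector_positions)
        probe.create_dataset("wavelengths", data=np.asarray(wl))
        labels = sorted({lab for _, lab in rec.annotations})
        for j, lab in enumerate(labels, start=1):
            stim = nirs.create_group(f"stim{j}")
            stim.create_dataset("name", data=lab)
            onsets = [t for t, l in rec.annotations if l == lab]
            stim.create_dataset(
                "data", data=np.column_stack([onsets, np.zeros(len(onsets)), np.ones(len(onsets))])
            )
    return path


def load_recording(path: str | Path) -> RawRecording:
    """Read a recording written by :func:`save_recording` (or any minimal
    single-data-block SNIRF file with 3-D probe positions)."""
    with h5py.File(path, "r") as f:
        if "nirs" not in f:
            raise ValueError(f"{path}: not a SNIRF-style container (missing /nirs)")
        nirs = f["nirs"]
        if "probe" not in nirs:
            raise ValueError(f"{path}: missing probe group")
        if "data1" not in nirs:
            raise ValueError(f"{path}: missing data group")
        probe_g = nirs["probe"]
        wavelengths = tuple(float(w) for w in np.asarray(probe_g["wavelengths"]))
        data = nirs["data1"]
        intensity = np.asarray(data["dataTimeSeries"])
        tvec = np.asarray(data["time"])
        if len(tvec) < 2:
            raise ValueError(f"{path}: need at least two time points")
        fs = 1.0 / float(np.mean(np.diff(tvec)))
        ml_names = sorted(
            (k for k in data.keys() if k.startswith("measurementList")),
            key=lambda k: int(k[len("measurementList"):]),
        )
        channels = []
        for name in ml_names:
            ml = data[name]
            channels.append(
                (
                    int(np.asarray(ml["sourceIndex"])) - 1,
                    int(np.asarray(ml["detectorIndex"])) - 1,
                    wavelengths[int(np.asarray(ml["wavelengthIndex"])) - 1],
                )
            )
        probe = ProbeLayout(
            source_positions=np.asarray(probe_g["sourcePos3D"]),
            detector_positions=np.asarray(probe_g["detectorPos3D"]),
            channels=tuple(channels),
            wavelengths=wavelengths,
        )
        annotations: list[tuple[float, str]] = []
        for k in sorted(k for k in nirs.keys() if k.startswith("stim")):
            stim = nirs[k]
            name = stim["name"][()]
            if isinstance(name, bytes):
                name = name.decode()
            for row in np.atleast_2d(np.asarray(stim["data"])):
                annotations.append((float(row[0]), str(name)))
        annotations.sort(key=lambda a: a[0])
    return RawRecording(
        intensity=intensity, sampling_rate=fs, probe=probe, annotations=annotations
    )


def channel_table(probe: ProbeLayout) -> pd.DataFrame:
    """Channel list as a DataFrame (for CSV export)."""
    sep = channel_separations(probe)
    return pd.DataFrame(
        {
            "channel": np.arange(probe.n_channels),
            "source": [c[0] for c in probe.channels],
            "detector": [c[1] for c in probe.channels],
            "wavelength_nm": [c[2] for c in probe.channels],
            "separation_mm": sep,
        }
    )


def replay_stream(
    rec: RawRecording, speed_factor: float = np.inf
) -> Iterator[StreamSample]:
    """Replay a stored recording sample by sample.

    Stands in for a live acquisition inlet: emits every sample exactly once,
    in order, with ``timestamp = index / sampling_rate``.  With a finite
    ``speed_factor`` the generator sleeps so that wall-clock pacing is
    ``speed_factor`` times faster than real time; ``speed_factor=inf`` (the
    default) replays as fast as possible.
    """
    if not speed_factor > 0:
        raise ValueError("speed_factor must be positive")
    dt = 1.0 / rec.sampling_rate
    for i in range(rec.n_samples):
        if np.isfinite(speed_factor):
            _time.sleep(dt / speed_factor)
        yield StreamSample(timestamp=i * dt, values=rec.intensity[i])
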