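"""Synthetic fNIRS/DOT data: probe geometry, task-evoked recordings, and
spike+step motion artifacts.

The generator emulates a block-design motor-imagery study: a grid of optode
modules over the motor cortex, two-wavelength channels with source-detector
separations spanning roughly 10-40 mm, a canonical double-gamma hemodynamic
response locked to task annotations, sinusoidal physiology (cardiac,
respiration, Mayer waves), slow drift and white noise.  Intensity traces are
built by running the hemodynamics *forward* through the modified
Beer-Lambert relation, so the downstream OD conversion is exact by
construction.

Motion artifacts are modeled as a spike-shaped transient (peak at the
midpoint of its duration) followed by a step-shaped baseline shift, both
with random polarity, with amplitudes expressed in multiples of the
resting-state OD standard deviation and drawn uniformly from empirically
observed ranges: spike amplitude 25.53-46.93 x std, duration 0.40-1.05 s,
step amplitude 2.38-8.25 x std.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gamma as _gamma_dist

from .hemorecon import default_extinction_table, mbll_forward
from .recordings import ProbeLayout, RawRecording, channel_separations

__all__ = [
    "SPIKE_AMPLITUDE_RANGE",
    "SPIKE_DURATION_RANGE",
    "STEP_AMPLITUDE_RANGE",
    "MASpec",
    "TaskParadigm",
    "CleanSignalModel",
    "gen_probe",
    "double_gamma_hrf",
    "gen_clean_recording",
    "sample_ma_params",
    "render_ma",
    "contaminate_window",
    "SubjectData",
    "gen_dataset",
    "split_subjects",
]

# Empirical parameter ranges of the spike+step artifact model
# (multiples of resting-state OD standard deviation; seconds).
SPIKE_AMPLITUDE_RANGE = (25.53, 46.93)
SPIKE_DURATION_RANGE = (0.40, 1.05)
STEP_AMPLITUDE_RANGE = (2.38, 8.25)


@dataclass(frozen=True)
class MASpec:
    """One synthetic motion artifact on the standardized-OD scale."""

    onset: float
    spike_amplitude: float
    spike_duration: float
    spike_polarity: int
    step_amplitude: float
    step_polarity: int

    def __post_init__(self) -> None:
        lo, hi = SPIKE_DURATION_RANGE
        if not (lo <= self.spike_duration <= hi) and self.spike_duration != 0.0:
            raise ValueError(f"spike_duration {self.spike_duration} outside [{lo}, {hi}] s")
        lo, hi = SPIKE_AMPLITUDE_RANGE
        if not (lo <= self.spike_amplitude <= hi) and self.spike_amplitude != 0.0:
            raise ValueError(f"spike_amplitude {self.spike_amplitude} outside [{lo}, {hi}]")
        lo, hi = STEP_AMPLITUDE_RANGE
        if not (lo <= self.step_amplitude <= hi) and self.step_amplitude != 0.0:
            raise ValueError(f"step_amplitude {self.step_amplitude} outside [{lo}, {hi}]")
        if self.spike_polarity not in (-1, 1) or self.step_polarity not in (-1, 1):
            raise ValueError("polarities must be +1 or -1")
        if self.onset < 0:
            raise ValueError("onset must be non-negative")


@dataclass(frozen=True)
class TaskParadigm:
    """Block design: task blocks separated by rest, several repetitions per
    condition (default: 12 s motor-imagery task, 15 s rest, 10 repetitions
    per hand)."""

    task_duration: float = 12.0
    rest_duration: float = 15.0
    repetitions: int = 10
    conditions: tuple[str, ...] = ("left", "right")

    def __post_init__(self) -> None:
        if self.task_duration <= 0 or self.rest_duration <= 0:
            raise ValueError("durations must be positive")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


@dataclass(frozen=True)
class CleanSignalModel:
    """Parameters of the clean synthetic signal.

    Hemodynamic response: canonical double-gamma (peak 6 s, undershoot 16 s,
    undershoot ratio 1/6), scaled to per-trial peak concentration changes
    ``amp_hbo``/``amp_hbr`` (uM).  Physiological components are sinusoids
    with per-channel random phase; amplitudes are in OD units.  ``drift_amp_od``
    scales two very slow sinusoids (0.008/0.016 Hz); white noise is i.i.d.
    Gaussian per sample.  Baseline intensity level is drawn per channel in dB
    around ``baseline_db``.
    """

    hrf_peak_s: float = 6.0
    hrf_undershoot_s: float = 16.0
    hrf_undershoot_ratio: float = 1.0 / 6.0
    amp_hbo: float = 0.5
    amp_hbr: float = -0.17
    cardiac_freq: float = 1.1
    cardiac_amp_od: float = 2.0e-3
    resp_freq: float = 0.25
    resp_amp_od: float = 1.0e-3
    mayer_freq: float = 0.1
    mayer_amp_od: float = 8.0e-4
    drift_amp_od: float = 2.0e-3
    white_noise_od: float = 1.0e-3
    baseline_db: float = 100.0
    baseline_db_jitter: float = 3.0

    def __post_init__(self) -> None:
        for name in ("cardiac_amp_od", "resp_amp_od", "mayer_amp_od",
                     "drift_amp_od", "white_noise_od"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def max_frequency(self) -> float:
        return max(self.cardiac_freq, self.resp_freq, self.mayer_freq)


def gen_probe(
    n_modules: int = 12,
    grid_spacing_mm: float = 30.0,
    intra_module_offset_mm: float = 10.0,
    separation_range_mm: tuple[float, float] = (10.0, 40.0),
    wavelengths: tuple[float, float] = (735.0, 850.0),
) -> ProbeLayout:
    """Grid-of-modules probe emulating a wearable HD-DOT patch.

    Each module contributes one source at the module center and one detector
    offset by ``intra_module_offset_mm`` along x; channels are formed between
    every source-detector pair whose separation falls in
    ``separation_range_mm``, at both wavelengths.  Defaults give separations
    spanning 10-40 mm.
    """
    if n_modules < 1:
        raise ValueError("n_modules must be >= 1")
    if grid_spacing_mm <= 0:
        raise ValueError("grid spacing must be positive")
    n_cols = int(np.ceil(np.sqrt(n_modules)))
    centers = np.array(
        [
            (col * grid_spacing_mm, row * grid_spacing_mm, 0.0)
            for i in range(n_modules)
            for row, col in [divmod(i, n_cols)]
        ]
    )
    sources = centers.copy()
    detectors = centers + np.array([intra_module_offset_mm, 0.0, 0.0])
    lo, hi = separation_range_mm
    channels: list[tuple[int, int, float]] = []
    for s in range(n_modules):
        for d in range(n_modules):
            sep = float(np.linalg.norm(sources[s] - detectors[d]))
            if lo <= sep <= hi:
                for w in wavelengths:
                    channels.append((s, d, w))
    return ProbeLayout(
        source_positions=sources,
        detector_positions=detectors,
        channels=tuple(channels),
        wavelengths=wavelengths,
    )


def double_gamma_hrf(t: np.ndarray, peak_s: float = 6.0, undershoot_s: float = 16.0,
                     undershoot_ratio: float = 1.0 / 6.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response, peak-normalized to 1."""
    # shape/scale chosen so the gamma modes sit at peak_s and undershoot_s
    a1, a2 = 6.0, 16.0
    h = (_gamma_dist.pdf(t, a1, scale=peak_s / (a1 - 1))
         - undershoot_ratio * _gamma_dist.pdf(t, a2, scale=undershoot_s / (a2 - 1)))
    peak = np.max(np.abs(h))
    return h / peak if peak > 0 else h


def _trial_schedule(paradigm: TaskParadigm, initial_rest_s: float) -> list[tuple[float, str]]:
    """Onset times for each trial: conditions interleaved, task then rest."""
    onsets = []
    t = initial_rest_s
    for _ in range(paradigm.repetitions):
        for cond in paradigm.conditions:
            onsets.append((t, cond))
            t += paradigm.task_duration + paradigm.rest_duration
    return onsets


@dataclass
class GroundTruth:
    """Per-channel ground truth accompanying a synthetic recording."""

    clean_od: np.ndarray          # (T, n_ch) total clean delta-OD
    dhbo: np.ndarray              # (T, n_pairs) uM
    dhbr: np.ndarray              # (T, n_pairs) uM
    pair_channels: list[tuple[int, int]]  # per pair: channel ids (wl1, wl2)


def gen_clean_recording(
    probe: ProbeLayout,
    paradigm: TaskParadigm,
    model: CleanSignalModel,
    sampling_rate: float = 6.67,
    seed: int | np.random.Generator = 0,
    initial_rest_s: float = 30.0,
) -> tuple[RawRecording, GroundTruth]:
    """Generate one subject's task recording plus its ground truth.

    The record opens with ``initial_rest_s`` of rest (used downstream as the
    calibration window), followed by the block design.  Channels over the
    left half of the probe respond to the first condition and the right half
    to the second (a crude contralateral map); the evoked response is the
    double-gamma HRF convolved with the task boxcar, scaled to ``amp_hbo`` /
    ``amp_hbr`` and carried into OD through the forward MBLL per channel.
    Intensity is ``baseline * exp(-delta_OD)`` so intensities are strictly
    positive and the OD conversion recovers the truth exactly.
    """
    if sampling_rate <= 2 * model.max_frequency:
        raise ValueError(
            f"sampling rate {sampling_rate} Hz must exceed twice the highest "
            f"physiological frequency ({model.max_frequency} Hz)"
        )
    rng = np.random.default_rng(seed)
    schedule = _trial_schedule(paradigm, initial_rest_s)
    duration = schedule[-1][0] + paradigm.task_duration + paradigm.rest_duration
    n = int(round(duration * sampling_rate))
    t = np.arange(n) / sampling_rate
    n_ch = probe.n_channels
    seps = channel_separations(probe)
    table = default_extinction_table()

    # condition responses: boxcar convolved with HRF, peak-normalized per trial
    hrf_t = np.arange(0, 32.0, 1.0 / sampling_rate)
    hrf = double_gamma_hrf(hrf_t, model.hrf_peak_s, model.hrf_undershoot_s,
                           model.hrf_undershoot_ratio)
    responses: dict[str, np.ndarray] = {}
    for cond in paradigm.conditions:
        box = np.zeros(n)
        for onset, lab in schedule:
            if lab == cond:
                i0 = int(round(onset * sampling_rate))
                i1 = min(n, i0 + int(round(paradigm.task_duration * sampling_rate)))
                box[i0:i1] = 1.0
        r = np.convolve(box, hrf)[:n]
        peak = np.max(np.abs(r))
        responses[cond] = r / peak if peak > 0 else r

    # contralateral response map over source-detector midpoints
    pairs = probe.sd_pairs()
    pair_keys = sorted(pairs)
    mid_x = np.array(
        [
            0.5 * (probe.source_positions[s][0] + probe.detector_positions[d][0])
            for s, d in pair_keys
        ]
    )
    center_x = float(np.median(mid_x))
    dhbo = np.zeros((n, len(pair_keys)))
    dhbr = np.zeros((n, len(pair_keys)))
    cond_of_half = {True: paradigm.conditions[0], False: paradigm.conditions[-1]}
    for p, (s, d) in enumerate(pair_keys):
        cond = cond_of_half[mid_x[p] <= center_x]
        dhbo[:, p] = model.amp_hbo * responses[cond]
        dhbr[:, p] = model.amp_hbr * responses[cond]

    clean_od = np.zeros((n, n_ch))
    pair_channels: list[tuple[int, int]] = []
    for p, key in enumerate(pair_keys):
        by_wl = pairs[key]
        wl_sorted = tuple(sorted(by_wl))
        if len(wl_sorted) == 2:
            dod = mbll_forward(dhbo[:, p], dhbr[:, p], seps[by_wl[wl_sorted[0]]],
                               wl_sorted, table)  # (2, T)
            for k, w in enumerate(wl_sorted):
                clean_od[:, by_wl[w]] += dod[k]
            pair_channels.append((by_wl[wl_sorted[0]], by_wl[wl_sorted[1]]))

    # physiology + drift + white noise, per channel with random phases
    for ch in range(n_ch):
        phases = rng.uniform(0, 2 * np.pi, size=5)
        clean_od[:, ch] += (
            model.cardiac_amp_od * np.sin(2 * np.pi * model.cardiac_freq * t + phases[0])
            + model.resp_amp_od * np.sin(2 * np.pi * model.resp_freq * t + phases[1])
            + model.mayer_amp_od * np.sin(2 * np.pi * model.mayer_freq * t + phases[2])
            + model.drift_amp_od * (np.sin(2 * np.pi * 0.008 * t + phases[3])
                                    + 0.5 * np.sin(2 * np.pi * 0.016 * t + phases[4]))
        )
    if model.white_noise_od > 0:
        clean_od += rng.normal(0.0, model.white_noise_od, size=clean_od.shape)

    base_db = model.baseline_db + model.baseline_db_jitter * rng.uniform(-1, 1, size=n_ch)
    baseline = 10.0 ** (base_db / 10.0)
    intensity = baseline * np.exp(-clean_od)
    annotations = [(onset, lab) for onset, lab in schedule]
    rec = RawRecording(intensity=intensity, sampling_rate=sampling_rate,
                       probe=probe, annotations=annotations)
    return rec, GroundTruth(clean_od=clean_od, dhbo=dhbo, dhbr=dhbr,
                            pair_channels=pair_channels)


# ---------------------------------------------------------------------------
# Motion artifacts
# ---------------------------------------------------------------------------


def sample_ma_params(
    rng: np.random.Generator,
    window_length: int = 100,
    sampling_rate: float = 6.67,
) -> MASpec:
    """Draw one artifact: uniform amplitudes/duration within the empirical
    ranges, random +/-1 polarities, onset uniform so the spike fits the window."""
    duration = rng.uniform(*SPIKE_DURATION_RANGE)
    window_s = window_length / sampling_rate
    onset = rng.uniform(0.0, max(window_s - duration, 0.0))
    return MASpec(
        onset=onset,
        spike_amplitude=rng.uniform(*SPIKE_AMPLITUDE_RANGE),
        spike_duration=duration,
        spike_polarity=int(rng.choice([-1, 1])),
        step_amplitude=rng.uniform(*STEP_AMPLITUDE_RANGE),
        step_polarity=int(rng.choice([-1, 1])),
    )


def render_ma(
    spec: MASpec,
    sampling_rate: float,
    window_length: int,
    spike_shape: str = "gaussian",
) -> np.ndarray:
    """Render one additive artifact trace (standardized-OD units).

    The spike is a compact transient of ``spike_duration`` whose extremum
    (``spike_polarity * spike_amplitude``) falls at the midpoint of its
    duration — implemented as a Gaussian truncated at +/-3 sigma mapped onto
    the duration (or a symmetric triangle).  The step begins where the spike
    ends and persists to the window end.  The trace is zero before onset.
    """
    t = np.arange(window_length) / sampling_rate
    end = spec.onset + spec.spike_duration
    if spec.spike_duration > 0 and end > window_length / sampling_rate + 0.5 / sampling_rate:
        raise ValueError("artifact extends past the window")
    trace = np.zeros(window_length)
    if spec.spike_amplitude != 0 and spec.spike_duration > 0:
        mid = spec.onset + spec.spike_duration / 2.0
        support = (t >= spec.onset) & (t <= end)
        if spike_shape == "gaussian":
            sigma = spec.spike_duration / 6.0  # +/-3 sigma spans the duration
            shape = np.exp(-0.5 * ((t - mid) / sigma) ** 2) * support
        elif spike_shape == "triangular":
            shape = np.clip(1.0 - np.abs(t - mid) / (spec.spike_duration / 2.0), 0.0, None)
        else:
            raise ValueError(f"unknown spike shape {spike_shape!r}")
        peak = shape.max()
        if peak > 0:
            # normalize on the sample grid so the discrete extremum equals the
            # specified amplitude, at the sample nearest the duration midpoint
            trace += spec.spike_polarity * spec.spike_amplitude * shape / peak
        else:  # duration shorter than one sample interval: lone-sample spike
            idx = int(round(mid * sampling_rate))
            if 0 <= idx < window_length:
                trace[idx] = spec.spike_polarity * spec.spike_amplitude
    if spec.step_amplitude != 0:
        trace += spec.step_polarity * spec.step_amplitude * (t >= end)
    return trace


def contaminate_window(
    clean_window: np.ndarray,
    spec: MASpec,
    sampling_rate: float,
    spike_shape: str = "gaussian",
) -> np.ndarray:
    """Add one rendered artifact to a standardized clean window."""
    clean_window = np.asarray(clean_window, dtype=float)
    return clean_window + render_ma(spec, sampling_rate, len(clean_window), spike_shape)


# ---------------------------------------------------------------------------
# Multi-subject datasets
# ---------------------------------------------------------------------------


@dataclass
class SubjectData:
    subject_id: int
    recording: RawRecording
    truth: GroundTruth


def split_subjects(n_subjects: int, seed: int | np.random.Generator = 0,
                   ratio: tuple[int, int, int] = (6, 1, 2)) -> dict[str, list[int]]:
    """Subject-wise train/val/test split, as close to ``ratio`` as integer
    counts allow (largest-remainder rounding); subjects are shuffled first."""
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects for a subject-wise split")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(n_subjects))
    total = sum(ratio)
    quotas = [n_subjects * r / total for r in ratio]
    counts = [int(np.floor(q)) for q in quotas]
    remainders = [q - c for q, c in zip(quotas, counts)]
    for i in sorted(range(3), key=lambda i: -remainders[i])[: n_subjects - sum(counts)]:
        counts[i] += 1
    names = ("train", "val", "test")
    split: dict[str, list[int]] = {}
    pos = 0
    for name, c in zip(names, counts):
        split[name] = sorted(int(s) for s in order[pos: pos + c])
        pos += c
    return split


def gen_dataset(
    n_subjects: int = 9,
    paradigm: TaskParadigm | None = None,
    model: CleanSignalModel | None = None,
    probe: ProbeLayout | None = None,
    sampling_rate: float = 6.67,
    seed: int = 0,
) -> tuple[list[SubjectData], dict[str, list[int]]]:
    """Generate per-subject recordings plus a subject-wise 6:1:2 split."""
    paradigm = paradigm or TaskParadigm()
    model = model or CleanSignalModel()
    probe = probe or gen_probe()
    rng = np.random.default_rng(seed)
    subjects = []
    for sid in range(n_subjects):
        rec, truth = gen_clean_recording(
            probe, paradigm, model, sampling_rate, seed=rng.integers(0, 2**31 - 1)
        )
        subjects.append(SubjectData(subject_id=sid, recording=rec, truth=truth))
    return subjects, split_subjects(n_subjects, seed=rng.integers(0, 2**31 - 1))
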