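"""Shared fixtures: a small probe, short synthetic recordings, and a
modestly trained denoiser reused by the unit tests (the acceptance tests
train their own full-scale model)."""

from __future__ import annotations

import numpy as np
import pytest

import dotstream as ds
from dotstream.dae import DenoisingAutoencoder, build_training_windows

FS = 6.67


@pytest.fixture(scope="session")
def probe():
    return ds.gen_probe(n_modules=4)


@pytest.fixture(scope="session")
def short_paradigm():
    return ds.TaskParadigm(repetitions=2)


@pytest.fixture(scope="session")
def recording(probe, short_paradigm):
    rec, truth = ds.gen_clean_recording(
        probe, short_paradigm, ds.CleanSignalModel(), FS, seed=11
    )
    return rec, truth


@pytest.fixture(scope="session")
def calibration(recording):
    rec, _ = recording
    return ds.calibrate(rec)


@pytest.fixture(scope="session")
def active_od(recording, calibration):
    """Clean OD of the active channels of the session recording."""
    rec, _ = recording
    act = calibration.active_channels
    return ds.od_convert(rec.intensity[:, act], calibration.intensity_mean[act])


@pytest.fixture(scope="session")
def small_model(active_od):
    """A quickly trained denoiser: enough to strictly beat no correction on
    synthetic windows, not the full-scale model of the acceptance run."""
    rng = np.random.default_rng(3)
    windows = build_training_windows([active_od], rng, sampling_rate=FS)
    model = DenoisingAutoencoder(epochs=60, seed=3)
    model.fit(windows.noisy, windows.clean)
    return model


@pytest.fixture(scope="session")
def training_windows(active_od):
    rng = np.random.default_rng(5)
    return build_training_windows([active_od], rng, sampling_rate=FS)
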