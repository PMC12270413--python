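"""Calibration statistics, pruning, OD conversion and causal filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dotstream as ds
from dotstream.preprocess import (
    CausalFilter,
    ZeroVarianceError,
    design_bandpass,
)


class TestDbAndSnr:
    @pytest.mark.parametrize("intensity,expected", [(1.0, 0.0), (10.0, 10.0), (100.0, 20.0)])
    def test_db_conversion(self, intensity, expected):
        assert ds.intensity_to_db(intensity) == pytest.approx(expected)

    def test_nonpositive_intensity_rejected(self):
        with pytest.raises(ValueError):
            ds.intensity_to_db(0.0)

    def test_snr_hand_computed(self):
        # mean 20, sample std sqrt(8/3) ~ 1.633 -> SNR ~ 12.247
        series = np.array([20.0, 22.0, 18.0, 20.0])
        assert ds.channel_snr(series) == pytest.approx(20.0 / np.sqrt(8.0 / 3.0))

    def test_snr_shift_under_intensity_scaling(self):
        rng = np.random.default_rng(0)
        intensity = rng.uniform(50, 60, size=200)
        i_db = ds.intensity_to_db(intensity)
        shifted = ds.intensity_to_db(10.0 * intensity)  # +10 dB, std unchanged
        np.testing.assert_allclose(shifted, i_db + 10.0)
        assert ds.channel_snr(shifted) == pytest.approx(
            (np.mean(i_db) + 10.0) / np.std(i_db, ddof=1)
        )

    def test_constant_series_flagged(self):
        with pytest.raises(ZeroVarianceError):
            ds.channel_snr(np.full(10, 20.0))

    def test_printed_convention_is_reciprocal(self):
        series = np.array([20.0, 22.0, 18.0, 20.0])
        assert ds.channel_snr(series, "std_over_mean") == pytest.approx(
            1.0 / ds.channel_snr(series)
        )


class TestPruning:
    def _block(self, mean_db, noise_db, n=200, seed=0):
        rng = np.random.default_rng(seed)
        return 10 ** ((mean_db + rng.normal(0, noise_db, size=n)) / 10.0)

    def test_power_range_rule(self):
        low = self._block(80.0, 0.1)       # below 85 dB -> pruned
        ok = self._block(100.0, 0.1)       # strong, stable -> active
        intensity = np.column_stack([low, ok])
        assert ds.prune_channels(intensity) == [1]

    def test_snr_rule(self):
        noisy = self._block(100.0, 15.0)   # SNR ~ 100/15 < 17.8 -> pruned
        ok = self._block(100.0, 1.0)       # SNR ~ 100 -> active
        assert ds.prune_channels(np.column_stack([noisy, ok])) == [1]

    def test_both_criteria_met(self):
        ok = self._block(100.0, 3.0)       # SNR ~ 33
        assert ds.prune_channels(ok[:, None]) == [0]

    def test_all_pruned_is_error(self):
        with pytest.raises(ValueError, match="pruned"):
            ds.prune_channels(self._block(150.0, 0.1)[:, None])

    def test_idempotent_and_order_independent(self):
        rng = np.random.default_rng(4)
        blocks = [self._block(db, 1.0, seed=i) for i, db in enumerate([100, 80, 110, 130])]
        intensity = np.column_stack(blocks)
        active = ds.prune_channels(intensity)
        again = ds.prune_channels(intensity[:, active])
        assert again == list(range(len(active)))
        perm = [3, 1, 0, 2]
        active_perm = ds.prune_channels(intensity[:, perm])
        assert sorted(perm[i] for i in active_perm) == active


class TestODConversion:
    @pytest.mark.parametrize(
        "ratio,expected", [(1.0, 0.0), (1.0 / np.e, 1.0), (np.e, -1.0)]
    )
    def test_known_ratios(self, ratio, expected):
        assert ds.od_convert(np.array([ratio]), 1.0)[0] == pytest.approx(expected)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            ds.od_convert(np.array([-1.0]), 1.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        dod=st.lists(st.floats(-2, 2), min_size=1, max_size=30),
        baseline=st.floats(1e-3, 1e6),
    )
    def test_forward_model_roundtrip(self, dod, baseline):
        """Generating intensity as baseline*exp(-dOD) then converting back
        recovers the OD change to float precision."""
        dod = np.array(dod)
        intensity = baseline * np.exp(-dod)
        np.testing.assert_allclose(ds.od_convert(intensity, baseline), dod, atol=1e-12)


class TestStandardize:
    def test_centered_series_is_zero(self):
        x = np.full(5, 3.3)
        np.testing.assert_array_equal(ds.standardize(x, 3.3, 1.0), np.zeros(5))

    def test_roundtrip_identity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(2.0, 5.0, size=100)
        np.testing.assert_allclose(
            ds.destandardize(ds.standardize(x, 2.0, 5.0), 2.0, 5.0), x, rtol=1e-15
        )

    def test_hand_example(self):
        np.testing.assert_array_equal(
            ds.standardize(np.array([1.0, 2.0, 3.0]), 2.0, 1.0), [-1.0, 0.0, 1.0]
        )

    def test_zero_std_rejected(self):
        with pytest.raises(ValueError):
            ds.standardize(np.ones(3), 1.0, 0.0)


@pytest.fixture(scope="module")
def coeffs():
    return design_bandpass(ds.FilterSpec(sampling_rate=6.67))


class TestBandpassDesign:

    def test_lowpass_minus3db_at_cutoff(self, coeffs):
        h = np.abs(
            np.squeeze(coeffs.frequency_response(np.array([0.5]), 6.67))
        )
        # high-pass is ~unity at 0.5 Hz, so cascade ~ 1/sqrt(2) there
        assert h == pytest.approx(1 / np.sqrt(2), rel=0.05)

    def test_dc_gain_zero(self, coeffs):
        h = coeffs.frequency_response(np.array([1e-9]), 6.67)
        assert np.abs(h)[0] == pytest.approx(0.0, abs=1e-6)

    def test_passband_gain(self, coeffs):
        h = np.abs(coeffs.frequency_response(np.array([0.2]), 6.67))[0]
        assert h >= 0.9

    def test_monotone_rolloff(self, coeffs):
        above = np.abs(coeffs.frequency_response(np.linspace(0.5, 3.0, 50), 6.67))
        assert np.all(np.diff(above) < 0)
        below = np.abs(coeffs.frequency_response(np.linspace(0.002, 0.05, 50), 6.67))
        assert np.all(np.diff(below) > 0)

    def test_sections_stable(self, coeffs):
        assert coeffs.is_stable()

    def test_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            ds.FilterSpec(sampling_rate=0.8)  # Nyquist 0.4 < 0.5 Hz low-pass


class TestCausalFilter:
    def test_streaming_equals_batch_bitwise(self):
        coeffs = design_bandpass(ds.FilterSpec(sampling_rate=6.67))
        rng = np.random.default_rng(0)
        x = rng.normal(size=(1000, 3))
        batch = CausalFilter(coeffs, 3).process(x)
        stream_filter = CausalFilter(coeffs, 3)
        chunks = [stream_filter.process(x[i: i + 1]) for i in range(1000)]
        np.testing.assert_array_equal(np.concatenate(chunks, axis=0), batch)

    def test_constant_input_decays_to_zero(self):
        coeffs = design_bandpass(ds.FilterSpec(sampling_rate=6.67))
        f = CausalFilter(coeffs, 1)
        y = f.process(np.ones((4000, 1)))
        assert np.abs(y[-1, 0]) < 1e-4
        assert np.abs(y[-1, 0]) < np.abs(y[100, 0])

    def test_zero_input_zero_state_zero_output(self):
        coeffs = design_bandpass(ds.FilterSpec(sampling_rate=6.67))
        y = CausalFilter(coeffs, 2).process(np.zeros((50, 2)))
        np.testing.assert_array_equal(y, 0.0)


class TestCalibrate:
    def test_statistics_over_expected_samples(self, probe):
        model = ds.CleanSignalModel()
        rec, _ = ds.gen_clean_recording(
            probe, ds.TaskParadigm(repetitions=1), model, 12.5, seed=0
        )
        cal = ds.calibrate(rec, calibration_s=30.0)
        n_cal = int(round(30.0 * 12.5))
        block = rec.intensity[:n_cal]
        np.testing.assert_allclose(cal.intensity_mean, block.mean(axis=0))
        np.testing.assert_allclose(cal.intensity_std, block.std(axis=0, ddof=1))

    def test_save_load_roundtrip(self, calibration, tmp_path):
        path = calibration.save(tmp_path / "cal.json")
        back = ds.CalibrationParams.load(path)
        np.testing.assert_array_equal(back.intensity_mean, calibration.intensity_mean)
        np.testing.assert_array_equal(back.od_std, calibration.od_std)
        assert back.active_channels == calibration.active_channels
        assert back.od_global_std == calibration.od_global_std
        np.testing.assert_array_equal(back.filter_coeffs.b_lp, calibration.filter_coeffs.b_lp)

    def test_active_list_matches_standalone_pruning(self, recording, calibration):
        rec, _ = recording
        n_cal = int(round(30.0 * rec.sampling_rate))
        assert calibration.active_channels == ds.prune_channels(rec.intensity[:n_cal])

    def test_short_channel_labels(self, calibration):
        np.testing.assert_array_equal(
            calibration.is_short_channel, calibration.separations_mm < 15.0
        )

    def test_too_short_recording_rejected(self, probe):
        rec = ds.RawRecording(
            intensity=np.ones((10, probe.n_channels)),
            sampling_rate=6.67,
            probe=probe,
        )
        with pytest.raises(ValueError, match="too short"):
            ds.calibrate(rec)
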