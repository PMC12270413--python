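"""MBLL conversions, the diffusion-model Jacobian, Tikhonov inversion and
block averaging."""

import numpy as np
import pytest

import dotstream as ds
from dotstream.hemorecon import (
    TikhonovReconstructor,
    _tikhonov_inverse,
    unmix_mua,
)

WL = (735.0, 850.0)


class TestMBLL:
    def test_zero_od_gives_zero_hb(self):
        hbo, hbr = ds.mbll(np.zeros(2), 30.0, WL)
        assert hbo == pytest.approx(0.0)
        assert hbr == pytest.approx(0.0)

    def test_forward_inverse_roundtrip(self):
        dod = ds.mbll_forward(1.0, -0.5, 30.0, WL)
        hbo, hbr = ds.mbll(dod, 30.0, WL)
        assert hbo == pytest.approx(1.0, rel=1e-12)
        assert hbr == pytest.approx(-0.5, rel=1e-12)

    def test_roundtrip_time_series(self):
        rng = np.random.default_rng(0)
        hbo_true = rng.normal(size=50)
        hbr_true = rng.normal(size=50)
        dod = ds.mbll_forward(hbo_true, hbr_true, 25.0, WL)
        hbo, hbr = ds.mbll(dod, 25.0, WL)
        np.testing.assert_allclose(hbo, hbo_true, atol=1e-12)
        np.testing.assert_allclose(hbr, hbr_true, atol=1e-12)

    def test_doubling_dpf_halves_outputs(self):
        table = ds.default_extinction_table()
        doubled = ds.ExtinctionTable(
            coefficients=table.coefficients,
            dpf={w: 2 * v for w, v in table.dpf.items()},
        )
        dod = np.array([0.01, 0.02])
        base = ds.mbll(dod, 30.0, WL, table)
        half = ds.mbll(dod, 30.0, WL, doubled)
        np.testing.assert_allclose(half, np.array(base) / 2.0)

    def test_nonpositive_separation_rejected(self):
        with pytest.raises(ValueError):
            ds.mbll(np.zeros(2), 0.0, WL)

    def test_singular_extinction_rejected(self):
        table = ds.ExtinctionTable(
            coefficients={WL[0]: (1.0, 1.0), WL[1]: (2.0, 2.0)},
            dpf={WL[0]: 6.0, WL[1]: 6.0},
        )
        with pytest.raises(ValueError, match="singular"):
            ds.mbll(np.zeros(2), 30.0, WL, table)


@pytest.fixture(scope="module")
def small_setup():
    probe = ds.gen_probe(n_modules=2)
    grid = ds.VoxelGrid(origin=(-15.0, -15.0, 0.0), pitch=5.0, shape=(12, 8, 6))
    return probe, grid, ds.build_jacobian(probe, grid)


class TestJacobian:
    def test_source_detector_swap_symmetry(self, small_setup):
        probe, grid, jac = small_setup
        s, d, w = probe.channels[0]
        swapped = ds.ProbeLayout(
            source_positions=np.array([probe.detector_positions[d]]),
            detector_positions=np.array([probe.source_positions[s]]),
            channels=((0, 0, w),),
            wavelengths=(w,),
        )
        jac_swapped = ds.build_jacobian(swapped, grid)
        np.testing.assert_allclose(
            jac_swapped.matrices[w][0], jac.matrices[w][0], rtol=1e-10
        )

    def test_peak_sensitivity_between_optodes_below_surface(self, small_setup):
        probe, grid, jac = small_setup
        w = probe.wavelengths[0]
        # pick a long channel (~30 mm)
        seps = ds.channel_separations(probe)
        idx_all = jac.channel_indices[w]
        row_pos = int(np.argmax(seps[idx_all]))
        ci = idx_all[row_pos]
        s, d, _ = probe.channels[ci]
        peak_voxel = grid.centers()[np.argmax(np.abs(jac.matrices[w][row_pos]))]
        src, det = probe.source_positions[s], probe.detector_positions[d]
        lo = min(src[0], det[0]) - grid.pitch
        hi = max(src[0], det[0]) + grid.pitch
        assert lo <= peak_voxel[0] <= hi
        assert peak_voxel[2] > 0  # below the surface

    def test_lateral_decay_away_from_axis(self, small_setup):
        probe, grid, jac = small_setup
        w = probe.wavelengths[0]
        row = np.abs(jac.matrices[w][0]).reshape(grid.shape)
        # profile along y at the depth/x of the row maximum
        ix, iy, iz = np.unravel_index(np.argmax(row), grid.shape)
        profile = row[ix, iy:, iz]
        assert np.all(np.diff(profile) <= 0)
        assert profile[-1] < profile[0]

    def test_finite_everywhere(self, small_setup):
        _, _, jac = small_setup
        for J in jac.matrices.values():
            assert np.all(np.isfinite(J))


class TestTikhonov:
    def test_identity_limit(self):
        J = np.eye(2)
        inv, alpha = _tikhonov_inverse(J, 1e-12)
        dy = np.array([3.0, -1.0])
        np.testing.assert_allclose(inv @ dy, dy, rtol=1e-9)

    def test_scalar_closed_form(self):
        J = np.eye(2)
        lam = 0.3
        inv, alpha = _tikhonov_inverse(J, lam)
        assert alpha == pytest.approx(1.0)
        dy = np.array([2.0, 4.0])
        np.testing.assert_allclose(inv @ dy, dy / (1 + lam), rtol=1e-12)

    def test_diagonal_zero_reg(self):
        J = np.diag([2.0, 1.0])
        inv, _ = _tikhonov_inverse(J, 0.0)
        np.testing.assert_allclose(inv @ np.array([2.0, 1.0]), [1.0, 1.0], atol=1e-12)

    def test_minimizes_penalized_objective(self):
        rng = np.random.default_rng(0)
        J = rng.normal(size=(4, 9))
        lam = 0.05
        inv, alpha = _tikhonov_inverse(J, lam)
        dy = rng.normal(size=4)
        x_star = inv @ dy
        # direct dense solve of the normal equations
        x_direct = np.linalg.solve(
            J.T @ J + lam * alpha * np.eye(9), J.T @ dy
        )
        np.testing.assert_allclose(x_star, x_direct, atol=1e-10)

    def test_zero_jacobian_rejected(self):
        with pytest.raises(ValueError):
            _tikhonov_inverse(np.zeros((2, 3)), 0.01)

    def test_convergence_to_direct_solve(self):
        rng = np.random.default_rng(1)
        J = np.eye(5) + 0.1 * rng.normal(size=(5, 5))  # well-conditioned
        dy = rng.normal(size=5)
        x_exact = np.linalg.solve(J, dy)
        inv, _ = _tikhonov_inverse(J, 1e-12)
        assert np.linalg.norm(inv @ dy - x_exact) / np.linalg.norm(x_exact) < 1e-6


class TestOperator:
    def test_truncation_to_all_channels_is_identity(self, small_setup):
        probe, _, jac = small_setup
        op = ds.invert_jacobian(jac, lam=0.01)
        trunc = ds.truncate_operator(op, list(range(probe.n_channels)))
        for w in op.inverse:
            np.testing.assert_allclose(trunc.inverse[w], op.inverse[w])

    def test_truncated_uses_only_active_measurements(self, small_setup):
        probe, _, jac = small_setup
        op = ds.invert_jacobian(jac)
        active = [int(c) for w in probe.wavelengths for c in jac.channel_indices[w][:2]]
        trunc = ds.truncate_operator(op, active)
        for w in probe.wavelengths:
            assert trunc.inverse[w].shape[1] == 2
        assert sorted(c for w in probe.wavelengths for c in trunc.active_channels[w]) \
            == sorted(active)

    def test_empty_active_set_rejected(self, small_setup):
        _, _, jac = small_setup
        op = ds.invert_jacobian(jac)
        with pytest.raises(ValueError):
            ds.truncate_operator(op, [])

    def test_save_roundtrip(self, small_setup, tmp_path):
        _, _, jac = small_setup
        op = ds.invert_jacobian(jac)
        path = op.save(tmp_path / "op.npz")
        with np.load(path) as data:
            w = list(op.inverse)[0]
            np.testing.assert_array_equal(data[f"inv_{w}"], op.inverse[w])


class TestReconstruction:
    def test_zero_measurement_zero_volume(self, small_setup):
        probe, grid, jac = small_setup
        op = ds.invert_jacobian(jac)
        dod = {w: np.zeros(inv.shape[1]) for w, inv in op.inverse.items()}
        hbo, hbr = ds.reconstruct_frame(op, dod)
        assert np.all(hbo == 0) and np.all(hbr == 0)

    def test_linearity(self, small_setup):
        probe, grid, jac = small_setup
        op = ds.invert_jacobian(jac)
        rng = np.random.default_rng(0)
        dod = {w: rng.normal(size=inv.shape[1]) for w, inv in op.inverse.items()}
        hbo1, hbr1 = ds.reconstruct_frame(op, dod)
        hbo3, hbr3 = ds.reconstruct_frame(op, {w: 3 * v for w, v in dod.items()})
        np.testing.assert_allclose(hbo3, 3 * hbo1, atol=1e-12)
        np.testing.assert_allclose(hbr3, 3 * hbr1, atol=1e-12)

    def test_forward_crime_localization(self, small_setup):
        """A point absorber forward-projected through J is reconstructed
        within two voxel pitches of its true location."""
        probe, grid, jac = small_setup
        op = ds.invert_jacobian(jac, lam=0.01)
        w = probe.wavelengths[0]
        J = jac.matrices[w]
        # true perturbation: voxel of highest total sensitivity at depth
        centers = grid.centers()
        depth_ok = centers[:, 2] > grid.pitch
        vox = int(np.argmax(np.abs(J).sum(axis=0) * depth_ok))
        x_true = np.zeros(grid.n_voxels)
        x_true[vox] = 1e-3
        dy = J @ x_true
        x_hat = np.abs(op.inverse[w] @ dy)
        com = (centers * x_hat[:, None]).sum(axis=0) / x_hat.sum()
        err = np.linalg.norm(com - centers[vox])
        assert err < 2 * grid.pitch

    def test_dimension_mismatch_rejected(self, small_setup):
        probe, _, jac = small_setup
        op = ds.invert_jacobian(jac)
        bad = {w: np.zeros(inv.shape[1] + 1) for w, inv in op.inverse.items()}
        with pytest.raises(ValueError, match="active-channel"):
            ds.reconstruct_frame(op, bad)

    def test_unmixing_inverts_extinction(self):
        table = ds.default_extinction_table()
        A = table.matrix(WL)
        hb_true = np.array([[1.0, -0.5], [0.2, 0.7]]).T  # (2, n_vox)
        dmua = {w: (A @ hb_true)[i] for i, w in enumerate(WL)}
        hbo, hbr = unmix_mua(dmua, table)
        np.testing.assert_allclose(hbo, hb_true[0], atol=1e-12)
        np.testing.assert_allclose(hbr, hb_true[1], atol=1e-12)


class TestTikhonovReconstructorEstimator:
    def test_fit_predict_shapes(self, small_setup):
        probe, grid, jac = small_setup
        rec = TikhonovReconstructor(lam=0.01).fit(jac)
        dod = {w: np.zeros(inv.shape[1]) for w, inv in rec.operator_.inverse.items()}
        out = rec.predict(dod)
        for w, x in out.items():
            assert x.shape == (grid.n_voxels,)

    def test_get_params_roundtrip(self):
        rec = TikhonovReconstructor(lam=0.02)
        assert rec.get_params() == {"lam": 0.02}
        rec.set_params(lam=0.5)
        assert rec.lam == 0.5


def test_volume_nifti_roundtrip(tmp_path):
    import nibabel as nib

    from dotstream.hemorecon import volume_to_nifti

    grid = ds.VoxelGrid(origin=(-10.0, 0.0, 0.0), pitch=5.0, shape=(4, 3, 2))
    vol = np.arange(grid.n_voxels, dtype=float)
    path = volume_to_nifti(vol, grid, tmp_path / "frame.nii.gz")
    img = nib.load(path)
    np.testing.assert_array_equal(np.asarray(img.dataobj), vol.reshape(grid.shape))
    assert img.affine[0, 0] == pytest.approx(5.0)
    assert img.affine[0, 3] == pytest.approx(-7.5)  # origin + half pitch


class TestBlockAverage:
    def test_identical_epochs_average_to_one_epoch(self):
        fs = 10.0
        t = np.arange(600) / fs
        template = np.sin(2 * np.pi * 0.2 * np.arange(100) / fs)
        series = np.zeros(600)
        onsets = [10.0, 30.0, 50.0]
        for onset in onsets:
            i = int(onset * fs)
            series[i: i + 100] += template
        annotations = [(o, "task") for o in onsets]
        t_ep, avg = ds.block_average(series, t, annotations, "task", pre_s=2.0, post_s=8.0)
        i0 = int(2.0 * fs)  # epoch sample at onset
        np.testing.assert_allclose(avg[i0 + 20], template[20], atol=1e-10)
        assert len(t_ep) == len(avg)

    def test_baseline_window_mean_is_zero(self):
        rng = np.random.default_rng(0)
        fs = 5.0
        series = rng.normal(size=500)
        t = np.arange(500) / fs
        annotations = [(40.0, "go"), (60.0, "go")]
        _, avg = ds.block_average(series, t, annotations, "go", pre_s=5.0, post_s=10.0)
        assert np.mean(avg[: int(5.0 * fs)]) == pytest.approx(0.0, abs=1e-12)

    def test_missing_condition_rejected(self):
        with pytest.raises(ValueError, match="no annotations"):
            ds.block_average(np.zeros(10), np.arange(10.0), [(1.0, "a")], "b", 1.0, 2.0)

    def test_epoch_out_of_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            ds.block_average(
                np.zeros(10), np.arange(10.0), [(1.0, "a")], "a", 5.0, 2.0
            )
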