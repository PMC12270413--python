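"""Channel-level hemodynamics (modified Beer-Lambert law) and 3D image
reconstruction via an analytic continuous-wave diffusion Jacobian with a
pre-computed Tikhonov-regularized inverse.

The MBLL converts two-wavelength optical-density changes into oxy-/deoxy-
hemoglobin concentration changes using specific absorption coefficients, the
source-detector separation and a differential path-length factor (DPF).  For
tomography, a sensitivity (Jacobian) matrix maps voxel-wise absorption
changes to channel-wise OD changes; the inverse problem is pre-solved with
zeroth-order Tikhonov regularization so that at stream time reconstruction is
a single matrix multiply.

The forward model here is the continuous-wave diffusion approximation in a
semi-infinite homogeneous medium with an extrapolated boundary, with adjoint
(Rytov) sensitivity — a standard analytic CW-DOT model that is swappable
behind the :class:`JacobianMatrix` interface.

Units: positions mm, absorption mm^-1, hemoglobin concentration uM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator

from .recordings import ProbeLayout, channel_separations

__all__ = [
    "ExtinctionTable",
    "default_extinction_table",
    "mbll",
    "mbll_forward",
    "VoxelGrid",
    "JacobianMatrix",
    "build_jacobian",
    "InverseOperator",
    "invert_jacobian",
    "truncate_operator",
    "reconstruct_frame",
    "unmix_mua",
    "TikhonovReconstructor",
    "volume_to_nifti",
    "block_average",
]

_LN10 = float(np.log(10.0))


@dataclass(frozen=True)
class ExtinctionTable:
    """Specific absorption coefficients and DPFs per wavelength.

    ``coefficients`` maps wavelength (nm) to ``(a_HbO, a_HbR)`` in
    mm^-1 uM^-1 (natural-log convention); ``dpf`` maps wavelength to the
    differential path-length factor (dimensionless).
    """

    coefficients: dict[float, tuple[float, float]]
    dpf: dict[float, float]

    def matrix(self, wavelengths: tuple[float, float]) -> np.ndarray:
        """2x2 extinction matrix [[a_HbO(l1), a_HbR(l1)], [a_HbO(l2), a_HbR(l2)]]."""
        A = np.array([self.coefficients[w] for w in wavelengths], dtype=float)
        if abs(np.linalg.det(A)) < 1e-18:
            raise ValueError(f"extinction matrix singular for wavelengths {wavelengths}")
        return A


def default_extinction_table() -> ExtinctionTable:
    """Extinction table for the 735/850 nm wavelength pair.

    Molar extinction coefficients are rounded values from the standard
    hemoglobin compilations (order 10^2-10^3 cm^-1 M^-1 in log10 convention),
    converted here to mm^-1 uM^-1 in the natural-log convention:
    a = eps[cm^-1/M] * ln(10) * 1e-7.  DPF defaults to 6.0 at both
    wavelengths; all values are configurable.
    """
    eps = {  # cm^-1 / M, log10 convention: (HbO2, Hb)
        735.0: (450.0, 1102.0),
        850.0: (1058.0, 691.3),
    }
    coeff = {w: (e[0] * _LN10 * 1e-7, e[1] * _LN10 * 1e-7) for w, e in eps.items()}
    return ExtinctionTable(coefficients=coeff, dpf={735.0: 6.0, 850.0: 6.0})


def mbll(
    dod: np.ndarray,
    separation_mm: float,
    wavelengths: tuple[float, float],
    table: ExtinctionTable | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Modified Beer-Lambert law: two-wavelength delta-OD -> (dHbO, dHbR) in uM.

    Solves ``[dHbO; dHbR] = A^-1 [dOD_l1/(D_l1 x); dOD_l2/(D_l2 x)]`` where
    ``A`` is the 2x2 extinction matrix, ``x`` the source-detector separation
    and ``D_l`` the DPF at wavelength ``l``.

    Parameters
    ----------
    dod : array, shape (2,) or (2, T)
        OD change at the two wavelengths (rows ordered like ``wavelengths``).
    """
    if not separation_mm > 0:
        raise ValueError("separation must be positive")
    table = table or default_extinction_table()
    A = table.matrix(wavelengths)
    dod = np.asarray(dod, dtype=float)
    path = np.array([table.dpf[w] * separation_mm for w in wavelengths])
    rhs = dod / (path[:, None] if dod.ndim == 2 else path)
    hb = np.linalg.solve(A, rhs)
    return hb[0], hb[1]


def mbll_forward(
    dhbo: np.ndarray,
    dhbr: np.ndarray,
    separation_mm: float,
    wavelengths: tuple[float, float],
    table: ExtinctionTable | None = None,
) -> np.ndarray:
    """Forward MBLL: (dHbO, dHbR) in uM -> delta-OD at the two wavelengths.

    Exact inverse of :func:`mbll`; also used by the synthetic generator to
    build intensity traces from ground-truth hemodynamics.
    """
    table = table or default_extinction_table()
    A = table.matrix(wavelengths)
    hb = np.stack([np.asarray(dhbo, float), np.asarray(dhbr, float)])
    path = np.array([table.dpf[w] * separation_mm for w in wavelengths])
    rhs = A @ hb
    return rhs * (path[:, None] if rhs.ndim == 2 else path)


# ---------------------------------------------------------------------------
# Forward model / Jacobian
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VoxelGrid:
    """Regular voxel grid in the tissue half-space (z >= 0 below the scalp).

    ``origin`` is the corner of the first voxel (mm), ``pitch`` the isotropic
    voxel edge (mm), ``shape`` the (nx, ny, nz) voxel counts.  ``mua`` and
    ``musp`` are the homogeneous background absorption and reduced scattering
    (mm^-1) of the diffusion model.
    """

    origin: tuple[float, float, float]
    pitch: float
    shape: tuple[int, int, int]
    mua: float = 0.01
    musp: float = 1.0

    def __post_init__(self) -> None:
        if not self.pitch > 0:
            raise ValueError("voxel pitch must be positive")

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    def centers(self) -> np.ndarray:
        """(n_voxels, 3) voxel-center coordinates, C-order (x fastest last)."""
        nx, ny, nz = self.shape
        ax = self.origin[0] + (np.arange(nx) + 0.5) * self.pitch
        ay = self.origin[1] + (np.arange(ny) + 0.5) * self.pitch
        az = self.origin[2] + (np.arange(nz) + 0.5) * self.pitch
        X, Y, Z = np.meshgrid(ax, ay, az, indexing="ij")
        return np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])


@dataclass(frozen=True)
class JacobianMatrix:
    """Per-wavelength channel x voxel sensitivity matrices tied to a probe."""

    probe: ProbeLayout
    grid: VoxelGrid
    matrices: dict[float, np.ndarray]  # wavelength -> (n_ch(w), n_voxels)
    channel_indices: dict[float, np.ndarray]  # wavelength -> probe channel ids


def _greens_semi_infinite(r_surf: np.ndarray, r: np.ndarray, mua: float, musp: float) -> np.ndarray:
    """CW fluence Green's function for a source at surface point ``r_surf``
    in a semi-infinite medium (z >= 0), extrapolated-boundary image method.

    The physical source sits one transport mean free path (z0 = 1/musp) below
    the surface; its negative image at -(z0 + 2*zb) with zb = 2*A*D (A = 1,
    refractive-index matched) enforces the boundary condition.
    """
    D = 1.0 / (3.0 * (mua + musp))
    mueff = np.sqrt(mua / D)
    z0 = 1.0 / musp
    zb = 2.0 * D  # A = 1
    src = np.asarray(r_surf, float).copy()
    src[2] = z0
    img = src.copy()
    img[2] = -(z0 + 2.0 * zb)
    d1 = np.linalg.norm(r - src, axis=-1)
    d2 = np.linalg.norm(r - img, axis=-1)
    floor = 0.5 / musp  # distance clamp: voxel coincident with an optode
    d1 = np.maximum(d1, floor)
    d2 = np.maximum(d2, floor)
    return (np.exp(-mueff * d1) / d1 - np.exp(-mueff * d2) / d2) / (4.0 * np.pi * D)


def build_jacobian(probe: ProbeLayout, grid: VoxelGrid) -> JacobianMatrix:
    """Adjoint (Rytov) sensitivity of every channel to voxel absorption changes.

    ``J[ch, vox] = G(source -> vox) * G(vox -> detector) / G(source -> detector)
    * voxel_volume`` for the semi-infinite homogeneous CW diffusion model.
    Rows are grouped per wavelength (optical properties are taken as equal
    across wavelengths by default; the grid carries them).
    """
    centers = grid.centers()
    vol = grid.pitch**3
    seps = channel_separations(probe)
    matrices: dict[float, np.ndarray] = {}
    chan_idx: dict[float, np.ndarray] = {}
    # cache per-optode fluence fields
    g_src = {
        i: _greens_semi_infinite(p, centers, grid.mua, grid.musp)
        for i, p in enumerate(probe.source_positions)
    }
    g_det = {
        i: _greens_semi_infinite(p, centers, grid.mua, grid.musp)
        for i, p in enumerate(probe.detector_positions)
    }
    for w in probe.wavelengths:
        idx = np.array([i for i, c in enumerate(probe.channels) if c[2] == w], dtype=int)
        J = np.empty((len(idx), grid.n_voxels))
        for row, ci in enumerate(idx):
            s, d, _ = probe.channels[ci]
            sd = _greens_semi_infinite(
                probe.source_positions[s], probe.detector_positions[d][None, :], grid.mua, grid.musp
            )[0]
            if sd <= 0:
                sd = _greens_semi_infinite(  # pragma: no cover - pathological geometry
                    probe.source_positions[s],
                    np.array([[0.0, 0.0, 1.0 / grid.musp]]) + probe.detector_positions[d],
                    grid.mua,
                    grid.musp,
                )[0]
            J[row] = g_src[s] * g_det[d] / sd * vol
            if not np.all(np.isfinite(J[row])):
                raise FloatingPointError(f"non-finite sensitivity for channel {ci} (sep {seps[ci]:.1f} mm)")
        matrices[w] = J
        chan_idx[w] = idx
    return JacobianMatrix(probe=probe, grid=grid, matrices=matrices, channel_indices=chan_idx)


# ---------------------------------------------------------------------------
# Tikhonov inversion
# ---------------------------------------------------------------------------


@dataclass
class InverseOperator:
    """Pre-computed Tikhonov pseudo-inverse of a Jacobian, truncated to the
    channels that survived pruning.

    ``inverse[w]`` is (n_voxels, n_active(w)); ``jacobian`` is retained so that
    truncation re-derives the inverse from the truncated forward matrix rather
    than slicing columns of an existing pseudo-inverse.
    """

    jacobian: JacobianMatrix
    lam: float
    inverse: dict[float, np.ndarray] = field(default_factory=dict)
    alpha: dict[float, float] = field(default_factory=dict)
    active_channels: dict[float, np.ndarray] = field(default_factory=dict)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        payload: dict[str, np.ndarray] = {"lam": np.array(self.lam)}
        for w in self.inverse:
            payload[f"inv_{w}"] = self.inverse[w]
            payload[f"act_{w}"] = self.active_channels[w]
            payload[f"alpha_{w}"] = np.array(self.alpha[w])
            payload[f"J_{w}"] = self.jacobian.matrices[w]
            payload[f"chidx_{w}"] = self.jacobian.channel_indices[w]
        np.savez(path, **payload)
        return path


def _tikhonov_inverse(J: np.ndarray, lam: float) -> tuple[np.ndarray, float]:
    """``J^T (J J^T + lam * alpha * I)^-1`` with ``alpha = max diag(J J^T)``.

    The ``alpha`` scaling makes the regularization hyperparameter relative to
    the largest channel self-sensitivity, so lam = 0.01 means 1% of it.
    """
    if J.size == 0 or not np.any(J):
        raise ValueError("degenerate all-zero Jacobian")
    JJt = J @ J.T
    alpha = float(np.max(np.diag(JJt)))
    reg = lam * alpha
    n = JJt.shape[0]
    Jinv = J.T @ np.linalg.solve(JJt + reg * np.eye(n), np.eye(n))
    return Jinv, alpha


def invert_jacobian(jac: JacobianMatrix, lam: float = 0.01) -> InverseOperator:
    """Pre-solve the inverse problem with zeroth-order Tikhonov regularization
    (default hyperparameter 0.01, scaled by max diag(J J^T))."""
    op = InverseOperator(jacobian=jac, lam=float(lam))
    for w, J in jac.matrices.items():
        op.inverse[w], op.alpha[w] = _tikhonov_inverse(J, lam)
        op.active_channels[w] = jac.channel_indices[w].copy()
    return op


def truncate_operator(op: InverseOperator, active: np.ndarray | list[int]) -> InverseOperator:
    """Restrict the operator to ``active`` probe channels.

    Recomputes the Tikhonov inverse from the row-truncated Jacobian (not a
    column slice of the full pseudo-inverse, which would no longer solve the
    reduced problem).
    """
    active = np.asarray(sorted(set(int(a) for a in active)), dtype=int)
    if active.size == 0:
        raise ValueError("active channel set is empty")
    out = InverseOperator(jacobian=op.jacobian, lam=op.lam)
    for w, J in op.jacobian.matrices.items():
        full_idx = op.jacobian.channel_indices[w]
        keep = np.isin(full_idx, active)
        if not np.any(keep):
            raise ValueError(f"no active channels at wavelength {w}")
        out.inverse[w], out.alpha[w] = _tikhonov_inverse(J[keep], op.lam)
        out.active_channels[w] = full_idx[keep]
    return out


def unmix_mua(
    dmua_by_wavelength: dict[float, np.ndarray], table: ExtinctionTable | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel spectral unmixing of absorption changes to (dHbO, dHbR) uM."""
    table = table or default_extinction_table()
    wl = tuple(sorted(dmua_by_wavelength))
    if len(wl) != 2:
        raise ValueError("need absorption maps at exactly two wavelengths")
    A = table.matrix(wl)  # dmua = A @ dHb (a in mm^-1/uM)
    stacked = np.stack([dmua_by_wavelength[w] for w in wl])
    hb = np.linalg.solve(A, stacked)
    return hb[0], hb[1]


def reconstruct_frame(
    op: InverseOperator,
    dod_by_wavelength: dict[float, np.ndarray],
    table: ExtinctionTable | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct one volumetric (dHbO, dHbR) frame from filtered delta-OD.

    ``dod_by_wavelength[w]`` must hold one value per *active* channel at that
    wavelength, ordered like ``op.active_channels[w]``.  Per-wavelength
    absorption maps are obtained as ``J^-1 . dy`` and then unmixed voxel-wise.
    """
    dmua: dict[float, np.ndarray] = {}
    for w, inv in op.inverse.items():
        dy = np.asarray(dod_by_wavelength[w], dtype=float)
        if dy.shape[0] != inv.shape[1]:
            raise ValueError(
                f"wavelength {w}: expected {inv.shape[1]} active-channel values, got {dy.shape[0]}"
            )
        dmua[w] = inv @ dy
    return unmix_mua(dmua, table)


class TikhonovReconstructor(BaseEstimator):
    """Scikit-learn style wrapper around the pre-computed linear inversion.

    ``fit`` takes a :class:`JacobianMatrix` (and optional active channel
    list) and pre-computes the regularized inverse; ``predict`` maps a
    channel-space measurement vector (or time x channel array) per wavelength
    to voxel-space absorption changes.
    """

    def __init__(self, lam: float = 0.01):
        self.lam = lam

    def fit(self, J: JacobianMatrix, active: np.ndarray | None = None) -> "TikhonovReconstructor":
        op = invert_jacobian(J, self.lam)
        if active is not None:
            op = truncate_operator(op, active)
        self.operator_ = op
        return self

    def predict(self, dod_by_wavelength: dict[float, np.ndarray]) -> dict[float, np.ndarray]:
        if not hasattr(self, "operator_"):
            raise RuntimeError("reconstructor is not fitted")
        return {w: inv @ np.asarray(dod_by_wavelength[w], float)
                for w, inv in self.operator_.inverse.items()}


def volume_to_nifti(volume: np.ndarray, grid: VoxelGrid, path: str | Path) -> Path:
    """Write a voxel map (flat or (nx, ny, nz)) as a NIfTI image whose affine
    encodes the grid's pitch and origin (mm)."""
    import nibabel as nib

    vol = np.asarray(volume, dtype=float).reshape(grid.shape)
    affine = np.diag([grid.pitch, grid.pitch, grid.pitch, 1.0])
    affine[:3, 3] = np.asarray(grid.origin) + grid.pitch / 2.0
    path = Path(path)
    nib.save(nib.Nifti1Image(vol, affine), path)
    return path


def block_average(
    series: np.ndarray,
    times: np.ndarray,
    annotations: list[tuple[float, str]],
    condition: str,
    pre_s: float,
    post_s: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Average peri-onset epochs of ``series`` across repetitions of a condition.

    ``series`` is (T, ...) sampled at ``times``; each epoch spans
    ``[-pre_s, +post_s]`` around an annotation onset and is baseline-shifted
    so the pre-onset mean is zero.  Returns (epoch_times, averaged_epoch).
    """
    onsets = [t for t, lab in annotations if lab == condition]
    if not onsets:
        raise ValueError(f"no annotations with label {condition!r}")
    dt = float(np.mean(np.diff(times)))
    n_pre = int(round(pre_s / dt))
    n_post = int(round(post_s / dt))
    epochs = []
    for onset in onsets:
        i0 = int(round((onset - times[0]) / dt))
        lo, hi = i0 - n_pre, i0 + n_post
        if lo < 0 or hi > len(times):
            raise ValueError(f"epoch around onset {onset:.2f} s exceeds record bounds")
        ep = np.asarray(series[lo:hi], dtype=float)
        base = ep[:n_pre].mean(axis=0) if n_pre > 0 else 0.0
        epochs.append(ep - base)
    avg = np.mean(epochs, axis=0)
    t_epoch = (np.arange(-n_pre, n_post)) * dt
    return t_epoch, avg
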