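"""Variable-flip-angle SPGR signal model and classical pixel-wise T1 fitting.

The spoiled gradient-echo (SPGR) steady-state signal at flip angle eta_k is

    M_k(T1, I0) = I0 * (1 - E1) * sin(eta_k) / (1 - E1 * cos(eta_k)),
    E1 = exp(-TR / T1),

with T1 the spin-lattice relaxation time (ms), TR the repetition time (ms)
and I0 the complex proton-density map.  Acquiring N_k >= 2 flip angles makes
(T1, |I0|) identifiable; the classical DESPOT1 approach linearizes the model
so that per-voxel linear regression recovers both.

Units: T1 and TR are milliseconds everywhere in this package; flip angles are
degrees at the API surface and radians internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "ParameterMaps",
    "AcquisitionSpec",
    "spgr_signal",
    "spgr_signal_jacobian",
    "despot1_fit",
    "nlls_fit",
]


@dataclass
class ParameterMaps:
    """The estimated MR parameter set: T1 (ms, real) and I0 (complex).

    Both maps share one spatial grid [Nx, Ny, Nz].  T1 must be strictly
    positive wherever it is defined; use :meth:`validate` before handing maps
    to the signal model.
    """

    t1: np.ndarray
    i0: np.ndarray

    def __post_init__(self) -> None:
        self.t1 = np.asarray(self.t1, dtype=np.float64)
        self.i0 = np.asarray(self.i0, dtype=np.complex128)
        if self.t1.shape != self.i0.shape:
            raise ValueError(
                f"t1 shape {self.t1.shape} != i0 shape {self.i0.shape}"
            )

    @property
    def shape(self) -> tuple:
        return self.t1.shape

    def validate(self) -> None:
        if not np.all(np.isfinite(self.t1)):
            raise ValueError("t1 contains non-finite values")
        if not np.all(np.isfinite(self.i0)):
            raise ValueError("i0 contains non-finite values")
        if np.any(self.t1 <= 0):
            raise ValueError("t1 must be strictly positive everywhere")

    def copy(self) -> "ParameterMaps":
        return ParameterMaps(self.t1.copy(), self.i0.copy())


@dataclass
class AcquisitionSpec:
    """vFA acquisition protocol: flip angles (deg), TR (ms), optional B1+ map.

    ``b1_scale`` multiplies the nominal flip angles voxel-wise
    (eta_eff = b1_scale * eta_k), the standard transmit-field compensation in
    vFA T1 mapping.  A scalar 1.0 means a perfectly homogeneous transmit field.
    """

    flip_angles_deg: np.ndarray
    tr_ms: float
    b1_scale: np.ndarray | float = 1.0

    def __post_init__(self) -> None:
        self.flip_angles_deg = np.atleast_1d(
            np.asarray(self.flip_angles_deg, dtype=np.float64)
        )
        self.tr_ms = float(self.tr_ms)
        if self.flip_angles_deg.size < 2:
            raise ValueError("need at least 2 flip angles for identifiability")
        if np.unique(self.flip_angles_deg).size != self.flip_angles_deg.size:
            raise ValueError("flip angles must be distinct")
        if np.any(self.flip_angles_deg <= 0) or np.any(self.flip_angles_deg > 90):
            raise ValueError("flip angles must lie in (0, 90] degrees")
        if self.tr_ms <= 0:
            raise ValueError("tr_ms must be positive")
        if np.any(np.asarray(self.b1_scale) <= 0):
            raise ValueError("b1_scale must be positive")

    @property
    def n_flip(self) -> int:
        return int(self.flip_angles_deg.size)

    def effective_angles_rad(self, grid_shape: tuple | None = None) -> np.ndarray:
        """Voxel-wise effective flip angles in radians, shape grid + [Nk]."""
        eta = np.deg2rad(self.flip_angles_deg)
        b1 = np.asarray(self.b1_scale, dtype=np.float64)
        if b1.ndim == 0:
            if grid_shape is None:
                return eta
            b1 = np.full(grid_shape, float(b1))
        elif grid_shape is not None and b1.shape != tuple(grid_shape):
            raise ValueError(f"b1_scale shape {b1.shape} != grid {grid_shape}")
        return b1[..., None] * eta


def _check_domain(maps: ParameterMaps, acq: AcquisitionSpec) -> None:
    maps.validate()
    if acq.tr_ms <= 0:
        raise ValueError("tr_ms must be positive")


def spgr_signal_at_angles(
    t1: np.ndarray, i0: np.ndarray, tr_ms: float, eta_rad: np.ndarray
) -> np.ndarray:
    """Raw SPGR evaluation at explicit effective angles (radians).

    ``eta_rad`` is broadcast against ``t1[..., None]``; an angle of exactly 0
    yields exactly 0 signal.  No protocol-level validation is applied — use
    :func:`spgr_signal` for checked evaluation.
    """
    if tr_ms <= 0:
        raise ValueError("tr_ms must be positive")
    t1 = np.asarray(t1, dtype=np.float64)
    if np.any(t1 <= 0):
        raise ValueError("t1 must be strictly positive")
    e1 = np.exp(-tr_ms / t1)[..., None]
    return np.asarray(i0)[..., None] * (1.0 - e1) * np.sin(eta_rad) / (
        1.0 - e1 * np.cos(eta_rad)
    )


def spgr_signal(maps: ParameterMaps, acq: AcquisitionSpec) -> np.ndarray:
    """Evaluate the SPGR model; returns a complex stack [Nx, Ny, Nz, Nk]."""
    _check_domain(maps, acq)
    eta = acq.effective_angles_rad(maps.shape)  # grid + [Nk]
    return spgr_signal_at_angles(maps.t1, maps.i0, acq.tr_ms, eta)


def spgr_signal_jacobian(
    maps: ParameterMaps, acq: AcquisitionSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Analytic partials (dM/dT1, dM/dI0), each shaped [Nx, Ny, Nz, Nk].

    dM/dI0 is the unit-I0 signal (the model is linear in I0).  dM/dT1 follows
    the chain rule through E1 = exp(-TR/T1):

        dM/dE1 = I0 * sin(eta) * (cos(eta) - 1) / (1 - E1*cos(eta))**2
        dE1/dT1 = E1 * TR / T1**2
    """
    _check_domain(maps, acq)
    eta = acq.effective_angles_rad(maps.shape)
    t1 = maps.t1[..., None]
    e1 = np.exp(-acq.tr_ms / t1)
    sin_e, cos_e = np.sin(eta), np.cos(eta)
    denom = 1.0 - e1 * cos_e
    d_i0 = (1.0 - e1) * sin_e / denom  # complex only via I0; keep as real stack
    d_m_d_e1 = maps.i0[..., None] * sin_e * (cos_e - 1.0) / denom**2
    d_e1_d_t1 = e1 * acq.tr_ms / t1**2
    return d_m_d_e1 * d_e1_d_t1, d_i0.astype(np.complex128)


def despot1_fit(
    images: np.ndarray,
    acq: AcquisitionSpec,
    fit_mask: np.ndarray | None = None,
) -> tuple[ParameterMaps, np.ndarray]:
    """DESPOT1: linearized per-voxel T1/|I0| fit from multi-flip-angle images.

    Regresses y_k = S_k/sin(eta_k) on z_k = S_k/tan(eta_k); the slope s gives
    T1 = -TR/ln(s) and the intercept b gives |I0| = b/(1-s).  Magnitude images
    are used.  Voxels with slope outside (0, 1), degenerate regressors, or
    excluded by ``fit_mask`` are flagged invalid (returned mask False) and
    carry T1 = NaN rather than a clamped value.

    Returns (maps, valid_mask); maps.i0 is real-valued magnitude (phase is not
    recoverable from magnitude fitting).
    """
    images = np.asarray(images)
    if images.shape[-1] != acq.n_flip:
        raise ValueError("last axis of images must match the number of flip angles")
    if acq.n_flip < 2:
        raise ValueError("need at least 2 flip angles")
    grid = images.shape[:-1]
    mag = np.abs(images).astype(np.float64)
    eta = acq.effective_angles_rad(grid)
    y = mag / np.sin(eta)
    z = mag / np.tan(eta)
    # per-voxel simple linear regression along the last axis
    zm = z.mean(axis=-1, keepdims=True)
    ym = y.mean(axis=-1, keepdims=True)
    var_z = ((z - zm) ** 2).sum(axis=-1)
    cov_zy = ((z - zm) * (y - ym)).sum(axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = cov_zy / var_z
        intercept = ym[..., 0] - slope * zm[..., 0]
        t1 = -acq.tr_ms / np.log(slope)
        i0_mag = intercept / (1.0 - slope)
    valid = (
        np.isfinite(slope)
        & (slope > 0.0)
        & (slope < 1.0)
        & (var_z > 0.0)
        & np.isfinite(t1)
        & (t1 > 0.0)
    )
    if fit_mask is not None:
        valid &= np.asarray(fit_mask, dtype=bool)
    t1 = np.where(valid, t1, np.nan)
    i0_mag = np.where(valid, i0_mag, 0.0)
    maps = ParameterMaps(np.where(valid, t1, 1.0), i0_mag.astype(np.complex128))
    maps.t1 = np.where(valid, maps.t1, np.nan)  # keep NaN sentinel post-validate-shape
    return maps, valid


def nlls_fit(
    images: np.ndarray,
    acq: AcquisitionSpec,
    init: ParameterMaps | None = None,
    fit_mask: np.ndarray | None = None,
) -> tuple[ParameterMaps, np.ndarray]:
    """Per-voxel nonlinear least squares of |M(T1, I0)| to magnitude images.

    A robust alternative to :func:`despot1_fit`; agrees with it exactly on
    noiseless data.  ``init`` seeds the optimizer (DESPOT1 is used when
    omitted).  Non-convergent voxels are flagged invalid.  Loops voxel-wise;
    intended for small grids and spot checks, not whole volumes.
    """
    images = np.asarray(images)
    grid = images.shape[:-1]
    mag = np.abs(images).astype(np.float64)
    if init is None:
        init, init_valid = despot1_fit(images, acq, fit_mask)
    else:
        init_valid = np.isfinite(init.t1) & (init.t1 > 0)
    eta_all = acq.effective_angles_rad(grid)
    t1_out = np.full(grid, np.nan)
    i0_out = np.zeros(grid)
    valid = np.zeros(grid, dtype=bool)
    sel = init_valid if fit_mask is None else (init_valid & np.asarray(fit_mask, bool))
    for idx in np.argwhere(sel):
        vox = tuple(idx)
        s = mag[vox]
        eta = eta_all[vox]

        def resid(p, s=s, eta=eta):
            t1, i0 = p
            e1 = np.exp(-acq.tr_ms / t1)
            return i0 * (1 - e1) * np.sin(eta) / (1 - e1 * np.cos(eta)) - s

        p0 = (float(init.t1[vox]), float(np.abs(init.i0[vox])) or 1.0)
        try:
            res = least_squares(resid, p0, bounds=([1e-3, 0.0], [1e7, np.inf]))
        except ValueError:
            continue
        if res.success and np.isfinite(res.x).all():
            t1_out[vox], i0_out[vox] = res.x
            valid[vox] = True
    maps = ParameterMaps(np.where(valid, t1_out, 1.0), i0_out.astype(np.complex128))
    maps.t1 = np.where(valid, maps.t1, np.nan)
    return maps, valid
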