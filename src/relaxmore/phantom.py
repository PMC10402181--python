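"""Digital phantoms and simulated vFA acquisitions with known ground truth.

Generators here are pure functions of their parameters and seed, emulating
three regimes: a vial phantom (piecewise-constant T1 disks in a bath), a
brain-like object (nested WM/GM/CSF-valued tissue classes), and — via high
noise and few coils — a low-SNR flex-coil setup.  Noise is added in k-space
as i.i.d. complex Gaussian per coil and flip angle, matching the measurement
model f = U F C x + n.

Default tissue T1 values (WM 850 ms, GM 1400 ms, CSF 4000 ms at 3T) are
literature-typical settings, configurable per call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoding import (
    CoilSensitivities,
    KSpaceData,
    SamplingMask,
    fft2c,
    full_mask,
)
from .signal import AcquisitionSpec, ParameterMaps, spgr_signal

__all__ = [
    "PhantomTruth",
    "make_vial_phantom",
    "make_brain_like_phantom",
    "simulate_coils",
    "simulate_acquisition",
]


@dataclass
class PhantomTruth:
    """Ground-truth maps plus the region labels they were painted from.

    Label 0 is background (i0 = 0); every labeled voxel's T1 equals its
    region's entry in ``region_t1_ms``.
    """

    maps: ParameterMaps
    labels: np.ndarray
    region_t1_ms: dict

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.shape != self.maps.shape:
            raise ValueError("labels and maps must share one grid")

    @property
    def object_mask(self) -> np.ndarray:
        return self.labels > 0


def _grid_coords(grid: tuple) -> tuple[np.ndarray, np.ndarray]:
    nx, ny = grid[0], grid[1]
    x = (np.arange(nx) - (nx - 1) / 2.0) / nx
    y = (np.arange(ny) - (ny - 1) / 2.0) / ny
    return np.meshgrid(x, y, indexing="ij")


def _smooth_phase(grid: tuple, rng: np.random.Generator) -> np.ndarray:
    """Low-order (linear + quadratic) smooth phase map in radians."""
    xx, yy = _grid_coords(grid)
    c = rng.uniform(-1.0, 1.0, size=5)
    ph = c[0] * 0.5 + c[1] * xx + c[2] * yy + c[3] * (xx**2 - yy**2) + c[4] * xx * yy
    return ph[..., None] * np.ones(grid[2])


def _paint(
    labels: np.ndarray,
    region_t1: dict,
    rng: np.random.Generator,
    background_t1: float = 1000.0,
) -> ParameterMaps:
    """Build maps from labels: piecewise-constant T1, |i0| = 1 inside the
    object with a smooth low-order phase, i0 = 0 in the background."""
    t1 = np.full(labels.shape, background_t1)
    for lab, val in region_t1.items():
        t1[labels == lab] = val
    mag = (labels > 0).astype(np.float64)
    phase = _smooth_phase(labels.shape, rng)
    i0 = mag * np.exp(1j * phase)
    return ParameterMaps(t1, i0)


def make_vial_phantom(
    grid: tuple = (128, 128, 1),
    n_vials: int = 5,
    t1_values_ms: np.ndarray | None = None,
    bath_t1_ms: float = 700.0,
    seed: int = 0,
) -> PhantomTruth:
    """Circular bath containing ``n_vials`` non-overlapping vial disks.

    Labels: 0 background, 1 bath, 2..n_vials+1 the vials (so the label
    histogram has n_vials + 2 distinct values).  T1 is piecewise constant;
    ``t1_values_ms`` defaults to a 300–3000 ms spread across the vials.
    """
    if t1_values_ms is None:
        t1_values_ms = np.linspace(300.0, 3000.0, n_vials)
    t1_values_ms = np.asarray(t1_values_ms, dtype=np.float64)
    if t1_values_ms.size != n_vials:
        raise ValueError("need one T1 value per vial")
    nx, ny, nz = grid
    xx, yy = _grid_coords(grid)
    rr = np.sqrt(xx**2 + yy**2)
    bath_r = 0.42
    labels2d = np.zeros((nx, ny), dtype=np.int64)
    labels2d[rr <= bath_r] = 1
    ring_r = 0.24
    vial_r = min(0.09, ring_r * np.sin(np.pi / max(n_vials, 2)) * 0.9)
    if ring_r + vial_r >= bath_r:
        raise ValueError("vials do not fit inside the bath")
    centers = []
    for v in range(n_vials):
        th = 2 * np.pi * v / n_vials
        cx, cy = ring_r * np.cos(th), ring_r * np.sin(th)
        for (px, py) in centers:
            if np.hypot(cx - px, cy - py) < 2 * vial_r:
                raise ValueError("vials overlap; reduce n_vials or radius")
        centers.append((cx, cy))
        labels2d[(xx - cx) ** 2 + (yy - cy) ** 2 <= vial_r**2] = v + 2
    labels = np.repeat(labels2d[:, :, None], nz, axis=2)
    region_t1 = {1: float(bath_t1_ms)}
    region_t1.update({v + 2: float(t1_values_ms[v]) for v in range(n_vials)})
    rng = np.random.default_rng(seed)
    return PhantomTruth(_paint(labels, region_t1, rng), labels, region_t1)


def make_brain_like_phantom(
    grid: tuple = (128, 128, 1),
    seed: int = 0,
    t1_wm_ms: float = 850.0,
    t1_gm_ms: float = 1400.0,
    t1_csf_ms: float = 4000.0,
) -> PhantomTruth:
    """Brain-like object: an elliptical head with a cortical GM ribbon, WM
    interior, and two CSF ventricle-like lobes.  Labels: 0 background,
    1 WM, 2 GM, 3 CSF.  Seeded jitter varies the geometry between subjects."""
    nx, ny, nz = grid
    rng = np.random.default_rng(seed)
    xx, yy = _grid_coords(grid)
    ex, ey = 0.40 + rng.uniform(-0.02, 0.02), 0.33 + rng.uniform(-0.02, 0.02)
    tilt = rng.uniform(-0.15, 0.15)
    xr = xx * np.cos(tilt) + yy * np.sin(tilt)
    yr = -xx * np.sin(tilt) + yy * np.cos(tilt)
    head = (xr / ex) ** 2 + (yr / ey) ** 2 <= 1.0
    inner = (xr / (ex * 0.82)) ** 2 + (yr / (ey * 0.82)) ** 2 <= 1.0
    labels2d = np.zeros((nx, ny), dtype=np.int64)
    labels2d[head] = 2  # cortical ribbon
    labels2d[inner] = 1  # white matter core
    for sgn in (-1.0, 1.0):
        cx = sgn * (0.10 + rng.uniform(-0.02, 0.02))
        cy = rng.uniform(-0.03, 0.03)
        vent = ((xr - cx) / 0.055) ** 2 + ((yr - cy) / 0.11) ** 2 <= 1.0
        labels2d[vent & inner] = 3
    labels = np.repeat(labels2d[:, :, None], nz, axis=2)
    region_t1 = {1: float(t1_wm_ms), 2: float(t1_gm_ms), 3: float(t1_csf_ms)}
    return PhantomTruth(_paint(labels, region_t1, rng), labels, region_t1)


def simulate_coils(
    grid: tuple, n_coils: int, seed: int = 0, lobe_width: float = 0.7
) -> CoilSensitivities:
    """Smooth complex Gaussian-lobe sensitivities centered around the FOV
    perimeter, root-sum-of-squares normalized to 1.

    A single coil reduces to a constant magnitude-1 map.
    """
    if n_coils < 1:
        raise ValueError("need at least one coil")
    nx, ny, nz = grid
    xx, yy = _grid_coords(grid)
    rng = np.random.default_rng(seed)
    c = np.empty((nx, ny, nz, n_coils), dtype=np.complex128)
    for j in range(n_coils):
        th = 2 * np.pi * j / n_coils + rng.uniform(-0.2, 0.2)
        cx, cy = 0.55 * np.cos(th), 0.55 * np.sin(th)
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        mag = np.exp(-d2 / (2 * lobe_width**2))
        ph = rng.uniform(-np.pi, np.pi) + 1.5 * (yy * np.cos(th) - xx * np.sin(th))
        c[:, :, :, j] = (mag * np.exp(1j * ph))[:, :, None]
    rss = np.sqrt((np.abs(c) ** 2).sum(axis=-1, keepdims=True))
    return CoilSensitivities(c / rss)


def simulate_acquisition(
    truth: PhantomTruth,
    coils: CoilSensitivities,
    acq: AcquisitionSpec,
    mask: SamplingMask,
    noise_sigma: float = 0.0,
    seed: int = 0,
) -> tuple[KSpaceData, KSpaceData]:
    """Simulate f = U F C M(truth) + n; returns (fully sampled, undersampled).

    ``noise_sigma`` is the standard deviation per real/imaginary component of
    the complex Gaussian k-space noise, drawn independently per coil and flip
    angle.  Bit-reproducible given the seed.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    grid = truth.maps.shape
    if coils.c.shape[:3] != grid:
        raise ValueError("coil grid inconsistent with phantom grid")
    x = spgr_signal(truth.maps, acq)  # [Nx,Ny,Nz,Nk]
    cx = coils.c[..., :, None] * x[..., None, :]
    f_full = fft2c(cx)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        n = rng.standard_normal(f_full.shape) + 1j * rng.standard_normal(f_full.shape)
        f_full = f_full + noise_sigma * n
    nk = acq.n_flip
    fm = full_mask(grid[0], grid[1], nk, nz=grid[2])
    full = KSpaceData(f_full, fm, coils, acq)
    under = KSpaceData(
        mask.u[:, :, :, None, :] * f_full, mask, coils, acq
    )
    return full, under
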