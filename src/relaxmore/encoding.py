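"""Multi-coil Cartesian MRI encoding and k-space undersampling masks.

The encoding operator of accelerated multi-coil MRI is

    f = U F C x + n

with C the coil sensitivity maps, F the (unitary, centered) 2D discrete
Fourier transform applied slice-by-slice, U a binary sampling mask and n
complex Gaussian measurement noise.  The adjoint is
E^H f = sum_j conj(C_j) F^{-1} (U f_j); with the unitary FFT convention the
forward/adjoint pair passes the dot-product test to machine precision.

Array conventions (0-based, fixed throughout the package):
image stacks  [Nx, Ny, Nz, Nk], coils [Nx, Ny, Nz, Nc],
k-space       [Nkx, Nky, Nz, Nc, Nk], masks [Nkx, Nky, Nz, Nk]
(the mask z axis may have length 1 and broadcasts across slices).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal import AcquisitionSpec

__all__ = [
    "CoilSensitivities",
    "SamplingMask",
    "KSpaceData",
    "fft2c",
    "ifft2c",
    "forward_encode",
    "adjoint_encode",
    "make_cartesian_vd_mask",
    "make_poisson_disk_mask",
]

_AXES = (0, 1)


def fft2c(x: np.ndarray) -> np.ndarray:
    """Unitary centered 2D FFT over the first two axes."""
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(x, axes=_AXES), axes=_AXES, norm="ortho"),
        axes=_AXES,
    )


def ifft2c(f: np.ndarray) -> np.ndarray:
    """Inverse of :func:`fft2c` (also its adjoint)."""
    return np.fft.fftshift(
        np.fft.ifft2(np.fft.ifftshift(f, axes=_AXES), axes=_AXES, norm="ortho"),
        axes=_AXES,
    )


@dataclass
class CoilSensitivities:
    """Complex receive sensitivities, [Nx, Ny, Nz, Nc]."""

    c: np.ndarray

    def __post_init__(self) -> None:
        self.c = np.asarray(self.c, dtype=np.complex128)
        if self.c.ndim != 4:
            raise ValueError("coil array must be 4-D [Nx, Ny, Nz, Nc]")
        if not np.all(np.isfinite(self.c)):
            raise ValueError("coil sensitivities must be finite")

    @property
    def n_coils(self) -> int:
        return self.c.shape[-1]

    def rss(self) -> np.ndarray:
        return np.sqrt((np.abs(self.c) ** 2).sum(axis=-1))


@dataclass
class SamplingMask:
    """Binary per-flip-angle k-space selector, [Nkx, Nky, Nz, Nk]."""

    u: np.ndarray
    af_nominal: float
    scheme: str  # {"cartesian_vd_1d", "poisson_disk_2d", "full"}
    meta: dict = field(default_factory=dict)  # e.g. tuned radii, center size

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u)
        if self.u.ndim != 4:
            raise ValueError("mask must be 4-D [Nkx, Nky, Nz, Nk]")
        vals = np.unique(self.u)
        if not np.all(np.isin(vals, [0, 1])):
            raise ValueError("mask entries must be 0/1")
        self.u = self.u.astype(np.float64)

    @property
    def n_flip(self) -> int:
        return self.u.shape[-1]

    def sampling_fractions(self) -> np.ndarray:
        """Achieved sampled fraction per flip angle."""
        return self.u.mean(axis=(0, 1, 2))


@dataclass
class KSpaceData:
    """Measured multi-coil multi-flip-angle k-space plus its acquisition context."""

    f: np.ndarray
    mask: SamplingMask
    coils: CoilSensitivities
    acq: AcquisitionSpec

    def __post_init__(self) -> None:
        self.f = np.asarray(self.f, dtype=np.complex128)
        if self.f.ndim != 5:
            raise ValueError("k-space must be 5-D [Nkx, Nky, Nz, Nc, Nk]")
        nkx, nky, nz, nc, nk = self.f.shape
        if self.coils.c.shape != (nkx, nky, nz, nc):
            raise ValueError("coil shape inconsistent with k-space")
        mu = self.mask.u
        if mu.shape[:2] != (nkx, nky) or mu.shape[3] != nk:
            raise ValueError("mask shape inconsistent with k-space")
        if mu.shape[2] not in (1, nz):
            raise ValueError("mask z axis must be 1 or Nz")
        if nk != self.acq.n_flip:
            raise ValueError("k-space flip-angle axis inconsistent with acquisition")
        if np.any(self.f[self._mask_b() == 0] != 0):
            raise ValueError("k-space must be exactly zero where the mask is zero")

    def _mask_b(self) -> np.ndarray:
        return np.broadcast_to(self.mask.u[:, :, :, None, :], self.f.shape)

    @property
    def grid_shape(self) -> tuple:
        return self.f.shape[:3]


def _check_encode_shapes(x, coils: CoilSensitivities, mask: SamplingMask) -> None:
    if x.ndim != 4:
        raise ValueError("image stack must be 4-D [Nx, Ny, Nz, Nk]")
    if coils.c.shape[:3] != x.shape[:3]:
        raise ValueError("coil grid inconsistent with image grid")
    if mask.u.shape[:2] != x.shape[:2] or mask.u.shape[3] != x.shape[3]:
        raise ValueError("mask inconsistent with image stack")
    if mask.u.shape[2] not in (1, x.shape[2]):
        raise ValueError("mask z axis must be 1 or Nz")


def forward_encode(
    x: np.ndarray, coils: CoilSensitivities, mask: SamplingMask
) -> np.ndarray:
    """Apply E = U F C to an image stack; returns k-space [.., Nc, Nk]."""
    x = np.asarray(x, dtype=np.complex128)
    _check_encode_shapes(x, coils, mask)
    cx = coils.c[..., :, None] * x[..., None, :]  # [Nx,Ny,Nz,Nc,Nk]
    return mask.u[:, :, :, None, :] * fft2c(cx)


def adjoint_encode(
    f: np.ndarray, coils: CoilSensitivities, mask: SamplingMask
) -> np.ndarray:
    """Apply E^H = C^H F^{-1} U; returns an image stack [Nx, Ny, Nz, Nk]."""
    f = np.asarray(f, dtype=np.complex128)
    if f.ndim != 5:
        raise ValueError("k-space must be 5-D [Nkx, Nky, Nz, Nc, Nk]")
    if coils.c.shape[:3] != f.shape[:3] or coils.c.shape[3] != f.shape[3]:
        raise ValueError("coil shape inconsistent with k-space")
    img = ifft2c(mask.u[:, :, :, None, :] * f)
    return (np.conj(coils.c)[..., :, None] * img).sum(axis=3)


def coilwise_zero_filled(f: np.ndarray, mask: SamplingMask) -> np.ndarray:
    """Per-coil zero-filled images F^{-1} U f, [Nx, Ny, Nz, Nc, Nk]."""
    return ifft2c(mask.u[:, :, :, None, :] * np.asarray(f, dtype=np.complex128))


# ---------------------------------------------------------------------------
# mask generators


def full_mask(nkx: int, nky: int, nk: int, nz: int = 1) -> SamplingMask:
    return SamplingMask(np.ones((nkx, nky, nz, nk)), af_nominal=1.0, scheme="full")


def make_cartesian_vd_mask(
    nkx: int,
    nky: int,
    af: float,
    n_center: int = 16,
    nk: int = 1,
    seed: int = 0,
    density_exponent: float = 3.0,
) -> SamplingMask:
    """1D Cartesian variable-density mask: full kx readout, undersampled ky.

    Exactly round(nky/af) phase-encode lines are kept per flip angle: the
    ``n_center`` central lines always, the rest drawn without replacement with
    polynomial-decay density (1 - d/dmax)**density_exponent in the distance d
    from the k-space center.  Each flip angle gets a distinct seeded
    realization; masks are bit-reproducible from the arguments.
    """
    if af < 1:
        raise ValueError("acceleration factor must be >= 1")
    if n_center >= nky:
        raise ValueError("n_center must be smaller than nky")
    n_lines = int(round(nky / af))
    if n_lines < n_center:
        raise ValueError(
            f"AF={af} with {n_center} central lines is infeasible: "
            f"would need {n_lines} total lines"
        )
    center = nky // 2
    c0 = center - n_center // 2
    central = np.arange(c0, c0 + n_center)
    outer = np.setdiff1d(np.arange(nky), central)
    d = np.abs(outer - center).astype(np.float64)
    w = (1.0 - d / (d.max() + 1.0)) ** density_exponent
    u = np.zeros((nkx, nky, 1, nk))
    rng = np.random.default_rng(seed)
    for k in range(nk):
        lines = central
        n_extra = n_lines - n_center
        if n_extra > 0:
            extra = rng.choice(outer, size=n_extra, replace=False, p=w / w.sum())
            lines = np.concatenate([central, extra])
        u[:, lines, 0, k] = 1.0
    return SamplingMask(
        u,
        af_nominal=float(af),
        scheme="cartesian_vd_1d",
        meta={"n_center": n_center, "n_lines": n_lines},
    )


def _bridson_mask(nkx: int, nky: int, radius: float, center_size: int, rng) -> np.ndarray:
    """Dart-throwing Poisson-disk sample on integer pixel sites, plus an
    all-ones central calibration block.  Accepted sites outside the block are
    pairwise at least ``radius`` apart in pixel units (checked on the snapped
    integer coordinates, so the guarantee holds on the emitted mask)."""
    u = np.zeros((nkx, nky), dtype=bool)
    cx0 = nkx // 2 - center_size // 2
    cy0 = nky // 2 - center_size // 2
    u[cx0 : cx0 + center_size, cy0 : cy0 + center_size] = True

    def in_block(px: int, py: int) -> bool:
        return cx0 <= px < cx0 + center_size and cy0 <= py < cy0 + center_size

    cell = max(radius, 1.0) / np.sqrt(2.0)
    gx, gy = int(np.ceil(nkx / cell)), int(np.ceil(nky / cell))
    grid = -np.ones((gx, gy), dtype=np.int64)
    pts: list[tuple[int, int]] = []
    r2 = radius * radius
    reach = int(np.ceil(radius / cell)) + 1

    def fits(px: int, py: int) -> bool:
        if u[px, py]:  # duplicate pixel site
            return False
        gi, gj = int(px / cell), int(py / cell)
        for ii in range(max(gi - reach, 0), min(gi + reach + 1, gx)):
            for jj in range(max(gj - reach, 0), min(gj + reach + 1, gy)):
                q = grid[ii, jj]
                if q >= 0:
                    dx, dy = pts[q][0] - px, pts[q][1] - py
                    if dx * dx + dy * dy < r2:
                        return False
        return True

    def accept(px: int, py: int) -> None:
        pts.append((px, py))
        grid[int(px / cell), int(py / cell)] = len(pts) - 1
        u[px, py] = True

    for _ in range(1000):
        px, py = int(rng.integers(nkx)), int(rng.integers(nky))
        if not in_block(px, py):
            accept(px, py)
            break
    active = [0]
    while active:
        i = int(rng.integers(len(active)))
        bx, by = pts[active[i]]
        placed = False
        for _ in range(30):
            rr = radius * (1.0 + rng.uniform())
            th = rng.uniform(0.0, 2.0 * np.pi)
            px = int(round(bx + rr * np.cos(th)))
            py = int(round(by + rr * np.sin(th)))
            if not (0 <= px < nkx and 0 <= py < nky) or in_block(px, py):
                continue
            if fits(px, py):
                accept(px, py)
                active.append(len(pts) - 1)
                placed = True
                break
        if not placed:
            active.pop(i)
    return u


def make_poisson_disk_mask(
    nkx: int,
    nky: int,
    af: float,
    center_size: int = 51,
    nk: int = 1,
    seed: int = 0,
    tol: float = 0.1,
) -> SamplingMask:
    """2D Poisson-disk mask with an all-ones central calibration block.

    The minimum-distance radius is auto-tuned by bisection so the total
    sampled fraction (center block included) lands within ``tol`` relative of
    1/af.  Each flip angle is an independent seeded realization.
    """
    if af < 1:
        raise ValueError("acceleration factor must be >= 1")
    if center_size**2 >= nkx * nky / af:
        raise ValueError(
            f"calibration block {center_size}x{center_size} alone exceeds the "
            f"sampling budget {nkx * nky / af:.0f} points at AF={af}"
        )
    target = 1.0 / af
    u = np.zeros((nkx, nky, 1, nk))
    if af == 1:
        return SamplingMask(
            np.ones((nkx, nky, 1, nk)),
            af_nominal=1.0,
            scheme="poisson_disk_2d",
            meta={"center_size": center_size, "radius": [0.0] * nk},
        )
    n_target = int(round(nkx * nky * target))
    radii = []
    for k in range(nk):
        # largest radius that still over-samples the budget; the surplus is
        # then randomly thinned, which cannot violate the minimum distance
        lo, hi = 0.75, max(nkx, nky) / 2.0  # radius bounds in pixels
        best = None  # (n_sampled, r, mask) with n_sampled >= n_target
        for it in range(25):
            r = 0.5 * (lo + hi)
            rng = np.random.default_rng((seed, k, it))
            m = _bridson_mask(nkx, nky, r, center_size, rng)
            n = int(m.sum())
            if n >= n_target:
                if best is None or r > best[1]:
                    best = (n, r, m)
                lo = r  # dense enough -> try sparser (larger radius)
            else:
                hi = r
            if hi - lo < 1e-3:
                break
        if best is None:
            raise ValueError(
                f"could not tune Poisson-disk radius for AF={af} with "
                f"center {center_size} on a {nkx}x{nky} grid"
            )
        n, r, m = best
        if n > n_target:
            c0x, c0y = nkx // 2 - center_size // 2, nky // 2 - center_size // 2
            blk = np.zeros_like(m)
            blk[c0x : c0x + center_size, c0y : c0y + center_size] = True
            outer = np.argwhere(m & ~blk)
            rng = np.random.default_rng((seed, k, 10_000))
            drop = rng.choice(len(outer), size=n - n_target, replace=False)
            m = m.copy()
            m[outer[drop, 0], outer[drop, 1]] = False
        radii.append(r)
        u[:, :, 0, k] = m
    return SamplingMask(
        u,
        af_nominal=float(af),
        scheme="poisson_disk_2d",
        meta={"center_size": center_size, "radius": radii},
    )
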