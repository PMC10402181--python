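"""Reconstruction quality metrics: PSNR, SSIM, NMSE, and a comparison harness.

All three metrics are evaluated against a reference map v* over a declared
evaluation mask (typically the object region):

    PSNR(v, v*) = 20 log10( max(v*) / sqrt(mean_N (v - v*)^2) )   [dB]
    SSIM(v, v*) = mean of (2 mu_v mu_v* + C1)(2 sigma_vv* + C2) /
                  ((mu_v^2 + mu_v*^2 + C1)(sigma_v^2 + sigma_v*^2 + C2))
    NMSE(v, v*) = ||v* - v||^2 / ||v*||^2

with C1 = (K1 L)^2, C2 = (K2 L)^2, K1 = 0.01, K2 = 0.03 and L the largest
reference magnitude over the mask.  SSIM local statistics use the customary
11-tap Gaussian window (sigma = 1.5, population covariance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .signal import ParameterMaps

__all__ = ["psnr", "ssim", "nmse", "compare_methods", "MetricReport"]

PSNR_INF = float("inf")  # sentinel for identical inputs


def _masked(v, v_star, mask):
    v = np.asarray(v, dtype=np.float64)
    v_star = np.asarray(v_star, dtype=np.float64)
    if v.shape != v_star.shape:
        raise ValueError(f"shape mismatch: {v.shape} vs {v_star.shape}")
    if mask is None:
        mask = np.ones(v.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != v.shape:
        raise ValueError("mask shape must match the maps")
    if not mask.any():
        raise ValueError("evaluation mask is empty")
    return v, v_star, mask


def psnr(v: np.ndarray, v_star: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Peak signal-to-noise ratio in dB over the mask; the peak is the masked
    maximum of the reference.  Identical inputs return the +inf sentinel."""
    v, v_star, mask = _masked(v, v_star, mask)
    mse = float(np.mean((v[mask] - v_star[mask]) ** 2))
    if mse == 0.0:
        return PSNR_INF
    peak = float(np.max(np.abs(v_star[mask])))
    return 20.0 * np.log10(peak / np.sqrt(mse))


def ssim(
    v: np.ndarray,
    v_star: np.ndarray,
    mask: np.ndarray | None = None,
    k1: float = 0.01,
    k2: float = 0.03,
    sigma: float = 1.5,
) -> float:
    """Mean structural similarity over the mask (Gaussian-windowed, 2D
    slice-wise).  The dynamic range L is the masked max |v*|."""
    v, v_star, mask = _masked(v, v_star, mask)
    L = float(np.max(np.abs(v_star[mask])))
    if L == 0.0:
        raise ValueError("reference map is identically zero on the mask")
    c1, c2 = (k1 * L) ** 2, (k2 * L) ** 2
    fargs = dict(sigma=sigma, truncate=3.5, mode="reflect")
    total, count = 0.0, 0
    # values outside the evaluation region are zeroed so windows straddling
    # the boundary compare methods on the same support
    v3 = (v * mask).reshape(v.shape[0], v.shape[1], -1)
    w3 = (v_star * mask).reshape(v.shape[0], v.shape[1], -1)
    m3 = mask.reshape(v.shape[0], v.shape[1], -1)
    for z in range(v3.shape[2]):
        a, b, m = v3[:, :, z], w3[:, :, z], m3[:, :, z]
        if not m.any():
            continue
        ua = gaussian_filter(a, **fargs)
        ub = gaussian_filter(b, **fargs)
        uaa = gaussian_filter(a * a, **fargs)
        ubb = gaussian_filter(b * b, **fargs)
        uab = gaussian_filter(a * b, **fargs)
        va, vb = uaa - ua**2, ubb - ub**2
        vab = uab - ua * ub
        s = ((2 * ua * ub + c1) * (2 * vab + c2)) / (
            (ua**2 + ub**2 + c1) * (va + vb + c2)
        )
        total += float(s[m].sum())
        count += int(m.sum())
    return total / count


def nmse(v: np.ndarray, v_star: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Normalized mean squared error ||v* - v||^2 / ||v*||^2 over the mask."""
    v, v_star, mask = _masked(v, v_star, mask)
    denom = float(np.sum(v_star[mask] ** 2))
    if denom == 0.0:
        raise ValueError("reference map has zero norm on the mask")
    return float(np.sum((v_star[mask] - v[mask]) ** 2)) / denom


@dataclass
class MetricReport:
    """Per-method T1-map metrics over one shared evaluation mask."""

    rows: list  # dicts: method, psnr_db, ssim, nmse
    mask: np.ndarray

    def as_dict(self) -> dict:
        return {r["method"]: {k: r[k] for k in ("psnr_db", "ssim", "nmse")}
                for r in self.rows}

    def to_csv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("method,psnr_db,ssim,nmse\n")
            for r in self.rows:
                fh.write(f"{r['method']},{r['psnr_db']:.6g},{r['ssim']:.6g},"
                         f"{r['nmse']:.6g}\n")


def compare_methods(
    truth: ParameterMaps,
    results: dict,
    mask: np.ndarray | None = None,
) -> MetricReport:
    """Score each method's T1 map against the ground truth.

    ``results`` maps method name -> ParameterMaps.  NaN-flagged invalid
    voxels (e.g. failed pixel-wise fits) are excluded from each method's
    evaluation via the shared mask intersected with finiteness.
    """
    if mask is None:
        mask = np.ones(truth.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != truth.shape:
        raise ValueError("mask shape must match the truth maps")
    rows = []
    for name, maps in results.items():
        if maps.shape != truth.shape:
            raise ValueError(f"method {name!r}: map shape {maps.shape} "
                             f"!= truth {truth.shape}")
        m = mask & np.isfinite(maps.t1)
        v = np.where(np.isfinite(maps.t1), maps.t1, 0.0)
        rows.append(
            dict(
                method=name,
                psnr_db=psnr(v, truth.t1, m),
                ssim=ssim(v, truth.t1, m),
                nmse=nmse(v, truth.t1, m),
            )
        )
    return MetricReport(rows=rows, mask=mask)
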