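"""File formats: HDF5 acquisition containers, NIfTI maps, YAML acquisition
specs, PNG mask exports, and model checkpoints.

One HDF5 file carries a complete simulated or measured acquisition
(/kspace, /mask, /coils datasets plus acquisition attributes); parameter maps
travel as NIfTI volumes, with complex I0 split into a magnitude/phase pair.
"""

from __future__ import annotations

import json

import h5py
import nibabel as nib
import numpy as np
import yaml

from .encoding import CoilSensitivities, KSpaceData, SamplingMask
from .signal import AcquisitionSpec, ParameterMaps
from .unrolled import UnrolledModel

__all__ = [
    "save_kspace_h5",
    "load_kspace_h5",
    "save_maps_nifti",
    "load_maps_nifti",
    "save_acq_yaml",
    "load_acq_yaml",
    "export_mask_png",
    "save_checkpoint",
    "load_checkpoint",
]


def save_kspace_h5(path: str, kdata: KSpaceData) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset("kspace", data=kdata.f)
        h5.create_dataset("mask", data=kdata.mask.u)
        h5.create_dataset("coils", data=kdata.coils.c)
        h5.attrs["flip_angles_deg"] = kdata.acq.flip_angles_deg
        h5.attrs["tr_ms"] = kdata.acq.tr_ms
        h5.attrs["mask_scheme"] = kdata.mask.scheme
        h5.attrs["mask_af_nominal"] = kdata.mask.af_nominal
        b1 = np.asarray(kdata.acq.b1_scale)
        if b1.ndim > 0:
            h5.create_dataset("b1_scale", data=b1)


def load_kspace_h5(path: str) -> KSpaceData:
    with h5py.File(path, "r") as h5:
        f = h5["kspace"][()]
        u = h5["mask"][()]
        c = h5["coils"][()]
        b1 = h5["b1_scale"][()] if "b1_scale" in h5 else 1.0
        acq = AcquisitionSpec(
            flip_angles_deg=h5.attrs["flip_angles_deg"],
            tr_ms=float(h5.attrs["tr_ms"]),
            b1_scale=b1,
        )
        mask = SamplingMask(
            u,
            af_nominal=float(h5.attrs["mask_af_nominal"]),
            scheme=str(h5.attrs["mask_scheme"]),
        )
    return KSpaceData(f, mask, CoilSensitivities(c), acq)


def save_maps_nifti(prefix: str, maps: ParameterMaps) -> list[str]:
    """Write T1 / |I0| / arg(I0) as three NIfTI files; returns the paths."""
    affine = np.eye(4)
    paths = []
    for suffix, arr in (
        ("t1", maps.t1),
        ("i0_mag", np.abs(maps.i0)),
        ("i0_phase", np.angle(maps.i0)),
    ):
        p = f"{prefix}_{suffix}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float64), affine), p)
        paths.append(p)
    return paths


def load_maps_nifti(prefix: str) -> ParameterMaps:
    t1 = nib.load(f"{prefix}_t1.nii.gz").get_fdata()
    mag = nib.load(f"{prefix}_i0_mag.nii.gz").get_fdata()
    ph = nib.load(f"{prefix}_i0_phase.nii.gz").get_fdata()
    return ParameterMaps(t1, mag * np.exp(1j * ph))


def save_acq_yaml(path: str, acq: AcquisitionSpec) -> None:
    doc = {
        "flip_angles_deg": [float(v) for v in acq.flip_angles_deg],
        "tr_ms": float(acq.tr_ms),
    }
    b1 = np.asarray(acq.b1_scale)
    doc["b1_scale"] = float(b1) if b1.ndim == 0 else "see HDF5 container"
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh)


def load_acq_yaml(path: str) -> AcquisitionSpec:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    b1 = doc.get("b1_scale", 1.0)
    if not isinstance(b1, (int, float)):
        b1 = 1.0
    return AcquisitionSpec(
        flip_angles_deg=np.asarray(doc["flip_angles_deg"], dtype=np.float64),
        tr_ms=float(doc["tr_ms"]),
        b1_scale=float(b1),
    )


def export_mask_png(path: str, mask: SamplingMask, flip_index: int = 0) -> None:
    """Dump one flip angle's mask as an 8-bit PNG for visual inspection."""
    import imageio.v3 as iio

    u = (mask.u[:, :, 0, flip_index] * 255).astype(np.uint8)
    iio.imwrite(path, u)


def save_checkpoint(path: str, model: UnrolledModel, extra: dict | None = None) -> None:
    """Portable checkpoint: one .npz of arrays plus a JSON sidecar recording
    the architecture hyperparameters (and any extra metadata)."""
    state = model.state()
    np.savez(path, **state)
    side = {"hyper": model.hyper, "extra": extra or {}}
    with open(_sidecar(path), "w") as fh:
        json.dump(side, fh, indent=1, default=float)


def load_checkpoint(path: str) -> dict:
    """Load a checkpoint into {'state': dict of arrays, 'hyper': dict}."""
    with np.load(path if path.endswith(".npz") else path + ".npz") as z:
        state = {k: z[k] for k in z.files}
    with open(_sidecar(path)) as fh:
        side = json.load(fh)
    return {"state": state, "hyper": side["hyper"], "extra": side.get("extra", {})}


def _sidecar(path: str) -> str:
    base = path[:-4] if path.endswith(".npz") else path
    return base + ".json"
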