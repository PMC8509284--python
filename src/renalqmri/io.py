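"""NIfTI + JSON sidecar persistence for phantoms, series and maps.

Every image artifact is written as a NIfTI-1 file with an isotropic
in-plane affine from the voxel size, accompanied by a ``.json`` sidecar
carrying the acquisition or provenance metadata (BIDS-flavoured field
names where a natural one exists: ``InversionTime``, ``EchoTime``,
``BValue``).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .phantom import PhantomImage, TissueParameterSet
from .relaxometry import ParameterMap
from .synthesis import AcquisitionSeries

__all__ = [
    "save_series",
    "load_series",
    "save_map",
    "load_map",
    "save_phantom",
    "load_phantom",
]

_PARAM_FIELD = {"IR_T1": "InversionTime", "ME_T2": "EchoTime", "DWI": "BValue"}


def _affine(voxel_size_mm=(1.0, 1.0)) -> np.ndarray:
    return np.diag([voxel_size_mm[0], voxel_size_mm[1], 1.0, 1.0])


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def save_series(series: AcquisitionSeries, base: str | Path, voxel_size_mm=(1.0, 1.0)) -> None:
    """Write a 4D series as ``<base>.nii`` plus ``<base>.json``."""
    base = Path(base)
    img = nib.Nifti1Image(series.data.astype(np.float32), _affine(voxel_size_mm))
    nib.save(img, str(base) + ".nii")
    meta = {
        "Kind": series.kind,
        _PARAM_FIELD[series.kind]: list(map(float, series.param_axis)),
        "RepetitionTime": series.tr_ms,
        "S0Scale": series.s0_scale,
        "SNR": None if np.isinf(series.snr) else series.snr,
        "Seed": series.seed,
        "InversionEfficiency": series.inv_eff,
    }
    _write_json(base.with_suffix(".json"), meta)


def load_series(base: str | Path) -> AcquisitionSeries:
    base = Path(base)
    meta = json.loads(base.with_suffix(".json").read_text())
    data = np.asarray(nib.load(str(base) + ".nii").dataobj, dtype=float)
    kind = meta["Kind"]
    return AcquisitionSeries(
        kind=kind,
        data=data,
        param_axis=np.asarray(meta[_PARAM_FIELD[kind]], dtype=float),
        tr_ms=meta.get("RepetitionTime"),
        s0_scale=meta["S0Scale"],
        snr=np.inf if meta.get("SNR") is None else meta["SNR"],
        seed=meta.get("Seed"),
        inv_eff=meta.get("InversionEfficiency", 1.0),
    )


def save_map(pmap: ParameterMap, base: str | Path, voxel_size_mm=(1.0, 1.0)) -> None:
    """Write values, mask and R^2 grids plus a JSON sidecar."""
    base = Path(base)
    aff = _affine(voxel_size_mm)
    nib.save(nib.Nifti1Image(pmap.values[..., None].astype(np.float32), aff), str(base) + ".nii")
    nib.save(
        nib.Nifti1Image(pmap.mask[..., None].astype(np.uint8), aff), str(base) + "_mask.nii"
    )
    q = np.where(np.isfinite(pmap.quality), pmap.quality, -1e30)
    nib.save(nib.Nifti1Image(q[..., None].astype(np.float32), aff), str(base) + "_r2.nii")
    _write_json(base.with_suffix(".json"), {"Kind": pmap.kind, "Meta": _jsonable(pmap.meta)})


def load_map(base: str | Path) -> ParameterMap:
    base = Path(base)
    meta = json.loads(base.with_suffix(".json").read_text())
    values = np.asarray(nib.load(str(base) + ".nii").dataobj, dtype=float)[..., 0]
    mask = np.asarray(nib.load(str(base) + "_mask.nii").dataobj).astype(bool)[..., 0]
    quality = np.asarray(nib.load(str(base) + "_r2.nii").dataobj, dtype=float)[..., 0]
    quality = np.where(quality <= -1e29, -np.inf, quality)
    return ParameterMap(
        kind=meta["Kind"], values=values, mask=mask, quality=quality, meta=meta.get("Meta", {})
    )


def save_phantom(phantom: PhantomImage, base: str | Path) -> None:
    """Write label map (int) and truth grids (float32) plus parameters."""
    base = Path(base)
    aff = _affine(phantom.voxel_size_mm)
    nib.save(nib.Nifti1Image(phantom.label_map[..., None].astype(np.int16), aff), str(base) + "_labels.nii")
    for name, grid in (
        ("t1", phantom.truth_t1), ("t2", phantom.truth_t2), ("adc", phantom.truth_adc)
    ):
        nib.save(nib.Nifti1Image(grid[..., None].astype(np.float32), aff), f"{base}_truth_{name}.nii")
    _write_json(
        base.with_suffix(".json"),
        {
            "Seed": phantom.seed,
            "VoxelSizeMm": list(phantom.voxel_size_mm),
            "TissueParameterSet": _jsonable(phantom.params.to_dict()),
        },
    )


def load_phantom(base: str | Path) -> PhantomImage:
    base = Path(base)
    meta = json.loads(base.with_suffix(".json").read_text())
    labels = np.asarray(nib.load(str(base) + "_labels.nii").dataobj).astype(np.int16)[..., 0]
    grids = {
        name: np.asarray(nib.load(f"{base}_truth_{name}.nii").dataobj, dtype=float)[..., 0]
        for name in ("t1", "t2", "adc")
    }
    pd_ = meta["TissueParameterSet"]
    from .phantom import Heterogeneity  # local import to keep module load light

    het = Heterogeneity(**pd_.pop("heterogeneity"))
    for k in ("t1_ms", "t2_ms", "adc_um2_per_ms"):
        pd_[k] = {int(c): v for c, v in pd_[k].items()}
    params = TissueParameterSet(heterogeneity=het, **pd_)
    return PhantomImage(
        label_map=labels,
        truth_t1=grids["t1"],
        truth_t2=grids["t2"],
        truth_adc=grids["adc"],
        voxel_size_mm=tuple(meta["VoxelSizeMm"]),
        seed=meta["Seed"],
        params=params,
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, float) and np.isinf(obj):
        return None
    return obj
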