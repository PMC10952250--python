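"""NIfTI / YAML / JSON plumbing.

On disk, 4-D dynamic series are NIfTI with axis order (x=col, y=row,
z=slice, t), float32; masks are uint8 NIfTI; protocols and configs are YAML.
In memory the package uses (slice, time, row, col) — these helpers own the
axis shuffle so nothing else has to.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

from .datatypes import DynamicSeries, GasProtocol, MaskSet, ValidationError


def _affine(voxel_size_mm: tuple[float, float, float]) -> np.ndarray:
    r, c, s = voxel_size_mm
    return np.diag([c, r, s, 1.0])


def save_series(series: DynamicSeries, path: str | Path) -> None:
    """Write a dynamic series as 4-D NIfTI (x, y, z, t), float32."""
    vol = np.transpose(series.data, (3, 2, 0, 1)).astype(np.float32)
    img = nib.Nifti1Image(vol, _affine(series.voxel_size_mm))
    img.header.set_zooms((*img.header.get_zooms()[:3], series.dynamic_interval_s))
    nib.save(img, str(path))


def load_series(
    path: str | Path,
    dynamic_interval_s: float | None = None,
    echo_index: int = 0,
    te_ms: float | None = None,
    allow_negative: bool = False,
) -> DynamicSeries:
    """Read a 4-D NIfTI written by :func:`save_series` (or equivalent)."""
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj, dtype=np.float64)
    if vol.ndim != 4:
        raise ValidationError(f"{path}: expected a 4-D NIfTI, got {vol.ndim}-D")
    data = np.transpose(vol, (2, 3, 1, 0))  # -> (slice, time, row, col)
    if dynamic_interval_s is None:
        zooms = img.header.get_zooms()
        dynamic_interval_s = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.5
    x, y, z = img.header.get_zooms()[:3]
    return DynamicSeries(
        data,
        dynamic_interval_s,
        echo_index=echo_index,
        te_ms=te_ms,
        voxel_size_mm=(float(y), float(x), float(z)),
        allow_negative=allow_negative,
    )


def save_mask(mask: np.ndarray, path: str | Path, voxel_size_mm=(3.0, 3.0, 10.0)) -> None:
    vol = np.transpose(np.asarray(mask, dtype=np.uint8), (2, 1, 0))
    nib.save(nib.Nifti1Image(vol, _affine(voxel_size_mm)), str(path))


def load_mask(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    vol = np.asarray(img.dataobj)
    if vol.ndim != 3:
        raise ValidationError(f"{path}: expected a 3-D mask NIfTI, got {vol.ndim}-D")
    return np.transpose(vol, (2, 1, 0)) > 0


def save_map(map3d: np.ndarray, path: str | Path, voxel_size_mm=(3.0, 3.0, 10.0)) -> None:
    """Write a 3-D map (e.g. a PSE map, percent) as float32 NIfTI."""
    vol = np.transpose(np.asarray(map3d, dtype=np.float32), (2, 1, 0))
    nib.save(nib.Nifti1Image(vol, _affine(voxel_size_mm)), str(path))


def load_masks(lung_path: str | Path, thoracic_path: str | Path) -> MaskSet:
    return MaskSet(lung=load_mask(lung_path), thoracic=load_mask(thoracic_path))


def save_protocol(protocol: GasProtocol, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "baseline_s": protocol.baseline_s,
                "gas_period_s": protocol.gas_period_s,
                "n_cycles": protocol.n_cycles,
                "dynamic_interval_s": protocol.dynamic_interval_s,
            },
            fh,
        )


def load_protocol(path: str | Path) -> GasProtocol:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return GasProtocol(
        baseline_s=float(d["baseline_s"]),
        gas_period_s=float(d["gas_period_s"]),
        n_cycles=int(d["n_cycles"]),
        dynamic_interval_s=float(d["dynamic_interval_s"]),
    )


def save_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
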