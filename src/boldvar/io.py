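"""NIfTI-1 and CSV input/output helpers."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import nibabel as nib
import numpy as np
import pandas as pd

from .types import BoldSeries, RigidTransform, VoiMask


def save_bold(series: BoldSeries, path: str | Path) -> None:
    affine = np.diag(list(series.voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(series.data.astype(np.float32), affine)
    img.header.set_zooms(tuple(series.voxel_size_mm) + (series.tr_seconds,))
    nib.save(img, str(path))


def load_bold(path: str | Path, tr_seconds: float | None = None) -> BoldSeries:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    zooms = img.header.get_zooms()
    if tr_seconds is None:
        tr_seconds = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.28
    voxel = tuple(float(z) for z in zooms[:3])
    return BoldSeries(data=data, voxel_size_mm=voxel, tr_seconds=tr_seconds)


def save_mask(mask: VoiMask, path: str | Path, voxel_size_mm=(1.0, 1.0, 1.0)) -> None:
    affine = np.diag(list(voxel_size_mm) + [1.0])
    img = nib.Nifti1Image(mask.data.astype(np.uint8), affine)
    nib.save(img, str(path))


def load_mask(path: str | Path, label: str = "placenta") -> VoiMask:
    img = nib.load(str(path))
    return VoiMask(data=np.asanyarray(img.dataobj) > 0, label=label)


def save_transforms_csv(transforms: Iterable[RigidTransform], path: str | Path) -> None:
    rows = [
        {"frame": t.frame_index, "slice": t.slice_index, "dx": t.dx, "dy": t.dy, "theta": t.theta}
        for t in transforms
    ]
    pd.DataFrame(rows, columns=["frame", "slice", "dx", "dy", "theta"]).to_csv(path, index=False)


def load_transforms_csv(path: str | Path) -> list[RigidTransform]:
    df = pd.read_csv(path)
    return [
        RigidTransform(int(r.frame), int(r.slice), float(r.dx), float(r.dy), float(r.theta))
        for r in df.itertuples()
    ]


def save_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serialisable: {type(x)}")
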