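"""File formats: TAC CSV round trips and NIfTI dynamic images with a
JSON frame-timing sidecar."""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .frames import FramingSchedule, TimeActivityCurve
from .voi import DynamicImage

__all__ = [
    "read_tac",
    "write_tac",
    "read_dynamic_image",
    "write_dynamic_image",
]

_TAC_COLUMNS = ["frame_start_s", "frame_end_s", "activity_kBq_per_ml"]


def write_tac(path: str | Path, tac: TimeActivityCurve) -> None:
    df = pd.DataFrame(
        {
            "frame_start_s": tac.schedule.start_s,
            "frame_end_s": tac.schedule.end_s,
            "activity_kBq_per_ml": tac.values,
        }
    )
    df.to_csv(path, index=False)


def read_tac(
    path: str | Path, role: str = "tissue", raw: bool = False
) -> TimeActivityCurve:
    """Read a TAC CSV (frame_start_s, frame_end_s, activity_kBq_per_ml)."""
    df = pd.read_csv(path)
    missing = [c for c in _TAC_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    for col in _TAC_COLUMNS:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            row = int(bad[0]) + 2 if len(bad) else "?"
            raise ValueError(f"{path}: non-numeric value in {col!r} near line {row}")
    for i, (a, b) in enumerate(zip(df["frame_start_s"], df["frame_end_s"])):
        if b <= a:
            raise ValueError(f"{path}: frame end <= start at line {i + 2}")
    try:
        schedule = FramingSchedule(tuple(zip(df["frame_start_s"], df["frame_end_s"])))
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
    return TimeActivityCurve(
        schedule=schedule,
        values=df["activity_kBq_per_ml"].to_numpy(dtype=float),
        role=role,
        raw=raw,
    )


def write_dynamic_image(
    prefix: str | Path, img: DynamicImage, masks: dict[str, np.ndarray] | None = None
) -> None:
    """Write ``<prefix>.nii`` (4D), ``<prefix>_frames.json`` sidecar and
    optional ``<prefix>_<name>_mask.nii`` volumes (uncompressed NIfTI)."""
    prefix = Path(prefix)
    affine = np.diag(list(img.voxel_size_mm) + [1.0])
    nib.save(nib.Nifti1Image(img.voxels, affine), str(prefix) + ".nii")
    sidecar = {
        "frame_start_s": [a for a, _ in img.schedule.frames],
        "frame_end_s": [b for _, b in img.schedule.frames],
        "units": "kBq/ml",
    }
    Path(str(prefix) + "_frames.json").write_text(json.dumps(sidecar, indent=1))
    for name, m in (masks or {}).items():
        nib.save(
            nib.Nifti1Image(np.asarray(m, dtype=np.uint8), affine),
            f"{prefix}_{name}_mask.nii",
        )


def read_dynamic_image(
    path_4d: str | Path, path_mask: str | Path | None = None
) -> tuple[DynamicImage, np.ndarray | None]:
    """Read a 4D NIfTI + JSON timing sidecar (and an optional 3D mask)."""
    path_4d = Path(path_4d)
    img = nib.load(str(path_4d))
    vox = np.asarray(img.dataobj, dtype=float)
    if vox.ndim != 4:
        raise ValueError(f"{path_4d}: expected a 4D image, got ndim={vox.ndim}")
    sidecar_path = path_4d.with_name(path_4d.name.replace(".nii", "") + "_frames.json")
    if not sidecar_path.exists():
        raise ValueError(f"missing frame-timing sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    schedule = FramingSchedule(
        tuple(zip(sidecar["frame_start_s"], sidecar["frame_end_s"]))
    )
    if len(schedule) != vox.shape[3]:
        raise ValueError(
            f"sidecar lists {len(schedule)} frames but image has {vox.shape[3]}"
        )
    zooms = img.header.get_zooms()[:3]
    dyn = DynamicImage(voxels=vox, schedule=schedule, voxel_size_mm=tuple(zooms))
    mask = None
    if path_mask is not None:
        m_img = nib.load(str(path_mask))
        mask = np.asarray(m_img.dataobj).astype(bool)
        if mask.shape != vox.shape[:3]:
            raise ValueError(
                f"mask shape {mask.shape} does not match image grid {vox.shape[:3]}"
            )
    return dyn, mask
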