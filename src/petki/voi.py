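"""VOI placement and TAC extraction on 4D dynamic images.

The sampling rule mirrors common hottest-pixel methodology: pick the
slice holding the hottest voxel of a reference image inside a search
region, take it together with its two neighbours (three consecutive
slices), and on each slice keep the five hottest voxels.  The mean of
those voxels per frame is the regional TAC.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .frames import FramingSchedule, TimeActivityCurve

__all__ = ["DynamicImage", "VoiMask", "sum_frames", "hottest_voxels_mask", "extract_tac"]


@dataclass(frozen=True)
class DynamicImage:
    """4D (x, y, z, frame) activity-concentration volume in kBq/ml."""

    voxels: np.ndarray
    schedule: FramingSchedule
    voxel_size_mm: tuple[float, float, float] = (3.18, 3.18, 3.0)

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=float)
        object.__setattr__(self, "voxels", vox)
        if vox.ndim != 4:
            raise ValueError(f"expected a 4D (x, y, z, frame) array, got ndim={vox.ndim}")
        if vox.shape[3] != len(self.schedule):
            raise ValueError(
                f"frame axis length {vox.shape[3]} != schedule length {len(self.schedule)}"
            )
        if not np.all(np.isfinite(vox)):
            raise ValueError("image contains non-finite voxels")


@dataclass(frozen=True)
class VoiMask:
    """Boolean VOI aligned to a DynamicImage grid, confined to
    consecutive z-slices."""

    mask: np.ndarray
    slice_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", mask)
        if mask.ndim != 3 or not mask.any():
            raise ValueError("VOI mask must be a nonempty 3D boolean array")
        zs = np.flatnonzero(mask.any(axis=(0, 1)))
        if set(zs) - set(self.slice_indices):
            raise ValueError("mask has voxels outside the declared slices")
        si = sorted(self.slice_indices)
        if si != list(range(si[0], si[-1] + 1)):
            raise ValueError("slice indices must be consecutive")

    @property
    def n_slices_used(self) -> int:
        return len(self.slice_indices)


def sum_frames(img: DynamicImage, frame_indices: Sequence[int]) -> np.ndarray:
    """Voxelwise sum over the selected frames (e.g. first nine 5-s
    frames, the 45-s bolus window used to localise the aorta)."""
    idx = list(frame_indices)
    if not idx:
        raise ValueError("empty frame index list")
    return np.asarray(img.voxels[..., idx].sum(axis=3))


def _top_indices(values: np.ndarray, coords: np.ndarray, n: int) -> np.ndarray:
    """Indices of the n largest values; ties broken by (z, y, x) order."""
    z, y, x = coords[:, 2], coords[:, 1], coords[:, 0]
    order = np.lexsort((x, y, z, -values))
    return order[:n]


def hottest_voxels_mask(
    ref_img: np.ndarray,
    search_region: np.ndarray,
    n_per_slice: int = 5,
    n_slices: int = 3,
    mode: str = "per_slice",
) -> VoiMask:
    """Hottest-voxel VOI on a 3D reference image.

    The slice containing the region's global maximum is taken with its
    neighbours to form ``n_slices`` consecutive slices (shifted inward
    at the region boundary); ``mode='per_slice'`` marks the
    ``n_per_slice`` hottest voxels on each slice (15 voxels by
    default), ``mode='total'`` marks ``n_per_slice`` voxels over the
    whole 3-slice window.  Ties resolve by ascending (z, y, x) index.
    """
    ref = np.asarray(ref_img, dtype=float)
    region = np.asarray(search_region, dtype=bool)
    if ref.ndim != 3 or region.shape != ref.shape:
        raise ValueError("reference image and search region must be aligned 3D arrays")
    if mode not in ("per_slice", "total"):
        raise ValueError(f"unknown mode {mode!r}")
    zs = np.flatnonzero(region.any(axis=(0, 1)))
    if len(zs) < n_slices:
        raise ValueError(
            f"search region spans {len(zs)} slice(s); need >= {n_slices}"
        )

    masked = np.where(region, ref, -np.inf)
    flat_max = np.unravel_index(np.argmax(masked), ref.shape)
    z_star = flat_max[2]
    z_lo = int(np.clip(z_star - n_slices // 2, zs.min(), zs.max() - n_slices + 1))
    window = list(range(z_lo, z_lo + n_slices))

    mask = np.zeros_like(region)
    if mode == "per_slice":
        for z in window:
            in_slice = np.argwhere(region[:, :, z])
            if len(in_slice) == 0:
                continue
            vals = ref[in_slice[:, 0], in_slice[:, 1], z]
            coords = np.column_stack(
                (in_slice[:, 0], in_slice[:, 1], np.full(len(in_slice), z))
            )
            top = _top_indices(vals, coords, n_per_slice)
            mask[coords[top, 0], coords[top, 1], coords[top, 2]] = True
    else:
        sub = np.zeros_like(region)
        sub[:, :, window] = region[:, :, window]
        coords = np.argwhere(sub)  # (x, y, z)
        vals = ref[coords[:, 0], coords[:, 1], coords[:, 2]]
        top = _top_indices(vals, coords, n_per_slice)
        mask[coords[top, 0], coords[top, 1], coords[top, 2]] = True
    return VoiMask(mask=mask, slice_indices=tuple(window))


def extract_tac(
    img: DynamicImage, mask: VoiMask | np.ndarray, role: str = "tissue"
) -> TimeActivityCurve:
    """Per-frame mean of the masked voxels."""
    m = mask.mask if isinstance(mask, VoiMask) else np.asarray(mask, dtype=bool)
    if m.shape != img.voxels.shape[:3]:
        raise ValueError("mask is not aligned to the image grid")
    if not m.any():
        raise ValueError("empty mask")
    values = img.voxels[m, :].mean(axis=0)
    raw = bool(np.any(values < 0))
    return TimeActivityCurve(
        schedule=img.schedule, values=values, role=role, raw=raw
    )
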