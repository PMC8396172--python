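"""Boundary-weighted tumor placement inside a lung mask.

Mouse lung tumors cluster along lung boundaries and near each other, so
candidate centers are sampled with probability proportional to the inverse
Euclidean distance to the nearest boundary of the *working* mask (the lung
mask minus already-placed tumors: each placement carves new boundaries and
so raises the odds of a neighbouring tumor).  A position is accepted only if
at most 10% of tumor voxels fall outside the lung mask and the tumor
overlaps no previously placed tumor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi

from ..core import BinaryMask

__all__ = ["PlacedTumor", "PlacementError", "boundary_weights", "sample_tumor_location", "place_tumor"]


class PlacementError(RuntimeError):
    """No admissible tumor position within the trial budget."""


@dataclass
class PlacedTumor:
    """A placed, transformed tumor instance on the scan grid."""

    template_id: int
    affine: np.ndarray
    centroid_mm: np.ndarray
    volume_mm3: float
    mask: BinaryMask
    outside_fraction: float


def boundary_weights(working: np.ndarray, min_distance_vox: float = 0.5) -> np.ndarray:
    """Sampling weights 1/d(x) on a working mask, d clamped at half a voxel.

    ``d`` is the Euclidean distance transform to the mask boundary; the clamp
    avoids infinite weight right at the boundary.
    """
    d = ndi.distance_transform_edt(working)
    w = np.zeros(working.shape, dtype=np.float64)
    inside = working.astype(bool)
    w[inside] = 1.0 / np.maximum(d[inside], min_distance_vox)
    return w


def _tumor_offsets(tumor_mask: BinaryMask) -> np.ndarray:
    coords = np.argwhere(tumor_mask.as_bool())
    if coords.size == 0:
        raise ValueError("tumor mask is empty")
    center = np.round(coords.mean(axis=0)).astype(int)
    return coords - center


def sample_tumor_location(
    lung_mask: BinaryMask,
    tumor_mask: BinaryMask,
    placed: list[PlacedTumor],
    rng: np.random.Generator,
    *,
    max_trials: int = 500,
    max_outside_fraction: float = 0.10,
) -> tuple[np.ndarray, BinaryMask, float]:
    """Draw an admissible tumor center; returns (center voxel, full-grid mask,
    outside-of-lung fraction).

    Raises :class:`PlacementError` when no admissible position is found in
    ``max_trials`` draws (e.g. the mask is smaller than the tumor).
    """
    lung = lung_mask.as_bool()
    occupied = np.zeros(lung.shape, dtype=bool)
    for p in placed:
        occupied |= p.mask.as_bool()
    working = lung & ~occupied
    if not working.any():
        raise PlacementError("no free lung voxels remain")
    weights = boundary_weights(working)
    flat = weights.ravel()
    prob = flat / flat.sum()
    candidates = rng.choice(flat.size, size=max_trials, p=prob)
    offsets = _tumor_offsets(tumor_mask)
    shape = np.array(lung.shape)
    for cand in candidates:
        center = np.array(np.unravel_index(cand, lung.shape))
        vox = center + offsets
        if np.any(vox < 0) or np.any(vox >= shape):
            continue
        idx = tuple(vox.T)
        outside = 1.0 - lung[idx].mean()
        if outside > max_outside_fraction:
            continue
        if occupied[idx].any():
            continue
        full = np.zeros(lung.shape, dtype=np.uint8)
        full[idx] = 1
        return center, lung_mask.like(full), float(outside)
    raise PlacementError(f"no admissible position after {max_trials} trials")


def place_tumor(
    lung_mask: BinaryMask,
    tumor_mask: BinaryMask,
    placed: list[PlacedTumor],
    rng: np.random.Generator,
    *,
    template_id: int = -1,
    affine: np.ndarray | None = None,
    max_trials: int = 500,
    max_outside_fraction: float = 0.10,
) -> PlacedTumor:
    """Sample a location and materialize the placed tumor on the scan grid."""
    center, full, outside = sample_tumor_location(
        lung_mask, tumor_mask, placed, rng,
        max_trials=max_trials, max_outside_fraction=max_outside_fraction,
    )
    centroid_mm = (
        np.argwhere(full.as_bool()).mean(axis=0) * lung_mask.spacing_mm
        + np.asarray(lung_mask.origin_mm)
    )
    return PlacedTumor(
        template_id=template_id,
        affine=np.eye(3) if affine is None else np.asarray(affine),
        centroid_mm=centroid_mm,
        volume_mm3=full.volume_mm3,
        mask=full,
        outside_fraction=outside,
    )
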