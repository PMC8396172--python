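"""Rule-based lung segmentation from an HU volume.

Pipeline: threshold at -175 HU (removes bone and soft tissue), morphological
closing + opening (fills vasculature/nodule holes, removes small debris),
26-connected region analysis, then rule-based selection.  A region is
rejected when it (1) is connected to the background air surrounding the
animal (cradle air), (2) has mean HU outside [-600, -175] (air-only regions
fall below), or (3) has physical volume outside [200, 1200] mm^3 (empirical
mouse lung range).  If more than two regions survive, regions are ranked by
the separation of a 2-means clustering of their voxel coordinates, favouring
regions with two distinct centers of mass (left + right lung).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from sklearn.cluster import KMeans

from .core import BinaryMask, CTVolume, get_logger

__all__ = [
    "RegionCandidate",
    "NoLungFoundError",
    "threshold_lung_candidates",
    "morph_refine",
    "analyze_regions",
    "select_lung_region",
    "segment_lungs",
    "LungSegParams",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT6 = ndi.generate_binary_structure(3, 1)
_log = get_logger("lungseg")


class NoLungFoundError(RuntimeError):
    """No candidate region satisfied the lung selection criteria."""


@dataclass(frozen=True)
class LungSegParams:
    hu_threshold: float = -175.0
    morph_radius_mm: float = 0.25
    mean_hu_range: tuple[float, float] = (-600.0, -175.0)
    volume_range_mm3: tuple[float, float] = (200.0, 1200.0)
    kmeans_restarts: int = 10
    kmeans_balance_min: float = 0.25
    kmeans_max_voxels: int = 20000
    kmeans_seed: int = 0


@dataclass
class RegionCandidate:
    """One 26-connected candidate region with its selection features."""

    label_id: int
    volume_mm3: float
    mean_hu: float
    touches_border: bool
    kmeans_center_distance_mm: float
    voxel_count: int


def threshold_lung_candidates(vol: CTVolume, hu_threshold: float = -175.0) -> BinaryMask:
    """Mask of voxels strictly below the HU threshold (air + lung)."""
    return BinaryMask((vol.voxels < hu_threshold).astype(np.uint8), vol.spacing_um, vol.origin_mm)


def _ball(radius_vox: int) -> np.ndarray:
    if radius_vox <= 0:
        return np.ones((1, 1, 1), dtype=bool)
    r = radius_vox
    zz, yy, xx = np.ogrid[-r : r + 1, -r : r + 1, -r : r + 1]
    return zz**2 + yy**2 + xx**2 <= r**2


def morph_refine(mask: BinaryMask, radius_mm: float = 0.25) -> BinaryMask:
    """Morphological closing then opening with a ball structuring element.

    Closing makes the mask internally continuous (vessels and nodules join the
    lung); opening removes isolated features smaller than the element.
    ``radius_mm = 0`` is the identity.
    """
    if radius_mm < 0:
        raise ValueError("radius_mm must be >= 0")
    extent_mm = min(mask.shape) * mask.spacing_mm
    if radius_mm >= extent_mm / 2:
        raise ValueError(f"radius {radius_mm} mm exceeds the volume extent {extent_mm} mm")
    r_vox = int(round(radius_mm / mask.spacing_mm))
    if r_vox == 0:
        return mask.like(mask.voxels.copy())
    ball = _ball(r_vox)
    m = mask.as_bool()
    m = ndi.binary_closing(m, structure=ball)
    m = ndi.binary_opening(m, structure=ball)
    return mask.like(m.astype(np.uint8))


def _background_air(vol: CTVolume, hu_threshold: float) -> np.ndarray:
    """The 6-connected sub-threshold component(s) touching the volume border."""
    air = vol.voxels < hu_threshold
    lab, n = ndi.label(air, structure=_STRUCT6)
    if n == 0:
        return np.zeros(vol.shape, dtype=bool)
    border_ids = set()
    for sl in (lab[0], lab[-1], lab[:, 0], lab[:, -1], lab[:, :, 0], lab[:, :, -1]):
        border_ids.update(np.unique(sl))
    border_ids.discard(0)
    if not border_ids:
        return np.zeros(vol.shape, dtype=bool)
    return np.isin(lab, sorted(border_ids))


def _kmeans_center_distance(coords_mm: np.ndarray, params: LungSegParams) -> float:
    """Separation of a balanced 2-means split of region coordinates (mm).

    Splits where the smaller cluster holds < 25% of the voxels are treated as
    a single center of mass (distance 0): "two groups of similar size".
    """
    n = len(coords_mm)
    if n < 2:
        return 0.0
    if n > params.kmeans_max_voxels:
        sel = np.random.default_rng(params.kmeans_seed).choice(n, params.kmeans_max_voxels, replace=False)
        coords_mm = coords_mm[sel]
        n = len(coords_mm)
    km = KMeans(
        n_clusters=2,
        n_init=params.kmeans_restarts,
        random_state=params.kmeans_seed,
    ).fit(coords_mm)
    counts = np.bincount(km.labels_, minlength=2)
    if counts.min() < params.kmeans_balance_min * n:
        return 0.0
    return float(np.linalg.norm(km.cluster_centers_[0] - km.cluster_centers_[1]))


def analyze_regions(
    mask: BinaryMask, vol: CTVolume, params: LungSegParams = LungSegParams()
) -> tuple[list[RegionCandidate], np.ndarray]:
    """26-connected labeling of the mask plus per-region selection features.

    Returns the candidate list and the label volume (ids match
    ``RegionCandidate.label_id``).  ``touches_border`` flags 26-adjacency to
    the background-air component of the *image* (sub-threshold air reaching
    the volume border).
    """
    if mask.shape != vol.shape:
        raise ValueError("mask and volume must share a grid")
    lab, n = ndi.label(mask.as_bool(), structure=_STRUCT26)
    if n == 0:
        return [], lab
    background = _background_air(vol, params.hu_threshold)
    background_dil = ndi.binary_dilation(background, structure=_STRUCT26)
    voxvol = mask.voxel_volume_mm3
    s_mm = mask.spacing_mm
    candidates = []
    means = ndi.labeled_comprehension(vol.voxels, lab, np.arange(1, n + 1), np.mean, float, np.nan)
    counts = np.bincount(lab.ravel(), minlength=n + 1)[1:]
    for lid in range(1, n + 1):
        region = lab == lid
        touches = bool(np.any(region & background_dil))
        coords = np.argwhere(region).astype(np.float64) * s_mm
        dist = _kmeans_center_distance(coords, params)
        candidates.append(
            RegionCandidate(
                label_id=lid,
                volume_mm3=float(counts[lid - 1] * voxvol),
                mean_hu=float(means[lid - 1]),
                touches_border=touches,
                kmeans_center_distance_mm=dist,
                voxel_count=int(counts[lid - 1]),
            )
        )
    return candidates, lab


def select_lung_region(
    candidates: list[RegionCandidate],
    label_volume: np.ndarray,
    mask_like: BinaryMask,
    params: LungSegParams = LungSegParams(),
) -> BinaryMask:
    """Apply the three rejection criteria, then the 2-means ranking.

    Survivors of the criteria are returned directly when at most two remain
    (left + right lung as separate components); otherwise the two regions
    with the largest 2-means center separation are kept.
    """
    lo_hu, hi_hu = params.mean_hu_range
    lo_v, hi_v = params.volume_range_mm3
    survivors = [
        c
        for c in candidates
        if not c.touches_border and lo_hu <= c.mean_hu <= hi_hu and lo_v <= c.volume_mm3 <= hi_v
    ]
    if not survivors:
        raise NoLungFoundError(
            f"no lung found: {len(candidates)} candidate region(s), none met the criteria"
        )
    if len(survivors) > 2:
        survivors = sorted(survivors, key=lambda c: c.kmeans_center_distance_mm, reverse=True)[:2]
        _log.info(
            "more than two candidate regions; kept the two with the largest 2-means separation"
        )
    keep = [c.label_id for c in survivors]
    out = np.isin(label_volume, keep).astype(np.uint8)
    return mask_like.like(out)


def segment_lungs(vol: CTVolume, params: LungSegParams = LungSegParams()) -> BinaryMask:
    """Full segmentation: threshold, refine, analyze, select."""
    raw = threshold_lung_candidates(vol, params.hu_threshold)
    refined = morph_refine(raw, params.morph_radius_mm)
    candidates, lab = analyze_regions(refined, vol, params)
    selected = select_lung_region(candidates, lab, refined, params)
    _log.info(
        "selected lung mask: %.1f mm^3 in %d component(s)",
        selected.volume_mm3,
        int(ndi.label(selected.as_bool(), structure=_STRUCT26)[1]),
    )
    return selected
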