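"""Simulated training-set assembly: magnification, cropping, manifests."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from ..core import BinaryMask, CTVolume, get_logger
from ..phantom import ThoraxPhantom, TumorTemplate
from .geometry import ConeBeamGeometry
from .insert import simulate_tumor_scan
from .placement import PlacementError

__all__ = ["SimulatedSet", "finalize_training_set", "generate_simulated_dataset"]

_log = get_logger("tumorsim")


def finalize_training_set(
    vol: CTVolume,
    labels: BinaryMask,
    lung_mask: BinaryMask,
    rng: np.random.Generator,
    *,
    pad_voxels: int = 30,
    magnification_range: tuple[float, float] = (0.9, 1.1),
) -> tuple[CTVolume, BinaryMask]:
    """Random +/-10% magnification, then crop to the lung box padded 30 voxels.

    One magnification factor is applied jointly to image, labels, and lung
    mask; the crop window is the lung-mask bounding box grown by
    ``pad_voxels`` per side and clamped at the borders.
    """
    mag = float(rng.uniform(*magnification_range))
    img = vol.voxels
    lab = labels.voxels
    lung = lung_mask.voxels
    if not np.isclose(mag, 1.0):
        img = ndi.zoom(img.astype(np.float32), mag, order=1, mode="nearest")
        lab = (ndi.zoom(lab.astype(np.float32), mag, order=1, mode="nearest") >= 0.5).astype(np.uint8)
        lung = (ndi.zoom(lung.astype(np.float32), mag, order=1, mode="nearest") >= 0.5).astype(np.uint8)
    if lung.any():
        bbox = ndi.find_objects(lung.astype(np.int32))[0]
        sl = tuple(
            slice(max(s.start - pad_voxels, 0), min(s.stop + pad_voxels, n))
            for s, n in zip(bbox, img.shape)
        )
    else:
        sl = tuple(slice(0, n) for n in img.shape)
    out_img = CTVolume(np.ascontiguousarray(img[sl]), vol.spacing_um)
    out_lab = BinaryMask(np.ascontiguousarray(lab[sl]), vol.spacing_um)
    return out_img, out_lab


@dataclass
class SimulatedSet:
    """One simulated training pair plus its provenance record."""

    image: CTVolume
    labels: BinaryMask
    set_id: int
    is_validation: bool
    tumors: list[dict] = field(default_factory=list)


def generate_simulated_dataset(
    phantoms: list[ThoraxPhantom],
    bank: list[TumorTemplate],
    rng: np.random.Generator,
    *,
    n_sets: int = 60,
    tumors_per_set: int = 2,
    n_validation: int = 13,
    method: str = "projection",
    geom: ConeBeamGeometry | None = None,
    finalize: bool = False,
    size_range_mm3: tuple[float, float] = (0.03, 70.0),
    min_tumor_mm3: float | None = None,
) -> tuple[list[SimulatedSet], dict]:
    """Build ``n_sets`` image/label pairs with ``tumors_per_set`` tumors each.

    The last ``n_validation`` sets are flagged for training validation.  The
    manifest records, per set, the host phantom, every tumor's template id,
    affine, centroid, volume, and outside-of-lung fraction, so a run is fully
    reproducible from (seed, config).
    """
    if not bank:
        raise ValueError("tumor bank is empty")
    if not (0 <= n_validation <= n_sets):
        raise ValueError("n_validation must be within [0, n_sets]")
    sets: list[SimulatedSet] = []
    manifest_sets = []
    for i in range(n_sets):
        phantom = phantoms[i % len(phantoms)]
        try:
            image, labels, placed = simulate_tumor_scan(
                phantom.image,
                phantom.lung_mask_truth,
                bank,
                rng,
                n_tumors=tumors_per_set,
                geom=geom,
                method=method,
                size_range_mm3=size_range_mm3,
                min_tumor_mm3=min_tumor_mm3,
            )
        except PlacementError as exc:
            raise PlacementError(f"set {i}: {exc}") from exc
        if finalize:
            image, labels = finalize_training_set(image, labels, phantom.lung_mask_truth, rng)
        is_val = i >= n_sets - n_validation
        tumor_records = [
            {
                "template_id": int(p.template_id),
                "affine": np.asarray(p.affine).tolist(),
                "centroid_mm": np.asarray(p.centroid_mm).tolist(),
                "volume_mm3": float(p.volume_mm3),
                "outside_fraction": float(p.outside_fraction),
            }
            for p in placed
        ]
        sets.append(SimulatedSet(image, labels, i, is_val, tumor_records))
        manifest_sets.append(
            {
                "set_id": i,
                "phantom_index": i % len(phantoms),
                "is_validation": is_val,
                "tumors": tumor_records,
            }
        )
    manifest = {
        "n_sets": n_sets,
        "tumors_per_set": tumors_per_set,
        "n_validation": n_validation,
        "method": method,
        "sets": manifest_sets,
    }
    _log.info("generated %d simulated sets (%d validation)", n_sets, n_validation)
    return sets, manifest
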