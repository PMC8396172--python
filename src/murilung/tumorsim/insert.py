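"""Projection-domain tumor insertion and the end-to-end simulation pass.

The acquisition is emulated exactly as for the original scan: the tumor
composite and the parenchyma it covers are forward projected in the same
cone-beam geometry, the original projections are edited
(``orig + A(tumor) - A(parenchyma)``), and the edited set is reconstructed
with FDK and bilateral-filtered.  Because the projector is linear in
attenuation, the edit is computed as a single projection of the attenuation
difference, which cancels exactly outside the tumor footprint.
"""

from __future__ import annotations

import numpy as np

from ..core import BinaryMask, CTVolume, HUCalibration, from_hounsfield
from ..phantom import TumorTemplate
from .augment import augment_tumor, retexture_tumor
from .fdk import fdk_reconstruct
from .filters import bilateral_filter
from .geometry import ConeBeamGeometry, GeometryError, ProjectionSet
from .placement import PlacedTumor, place_tumor
from .projector import forward_project, forward_project_attenuation

__all__ = ["insert_tumors_in_projections", "compose_tumor_volumes", "simulate_tumor_scan"]


def insert_tumors_in_projections(
    orig: ProjectionSet,
    tumor_vol: CTVolume,
    parenchyma_vol: CTVolume,
    cal: HUCalibration = HUCalibration(),
) -> ProjectionSet:
    """Edit projections: add the tumor volume, subtract the covered tissue.

    Both volumes live on the scan grid with the acquisition geometry of
    ``orig``; where they are equal the output is bit-identical to ``orig``.
    """
    if tumor_vol.shape != parenchyma_vol.shape or not np.isclose(
        tumor_vol.spacing_um, parenchyma_vol.spacing_um
    ):
        raise GeometryError("tumor and parenchyma volumes must share the scan grid")
    mu_diff = from_hounsfield(tumor_vol.voxels, cal, clamp=False) - from_hounsfield(
        parenchyma_vol.voxels, cal, clamp=False
    )
    if not np.any(mu_diff):
        return orig.copy()
    delta = forward_project_attenuation(mu_diff, tumor_vol, orig.geometry)
    return ProjectionSet(orig.views + delta.views, orig.geometry)


def compose_tumor_volumes(
    image: CTVolume,
    placed: list[PlacedTumor],
    textures: list[np.ndarray],
    soft_masks: list[np.ndarray],
) -> tuple[CTVolume, CTVolume, np.ndarray]:
    """Build the tumor composite and parenchyma volumes for insertion.

    Returns ``(tumor_vol, parenchyma_vol, blend)`` where ``blend`` is the
    voxelwise maximum of the soft masks.  Inside the blend support the tumor
    volume is ``w * texture + (1 - w) * original`` and the parenchyma volume
    is the original tissue, so their difference is exactly
    ``w * (texture - orig)``; outside the support both volumes are air
    (-1000 HU), which projects to zero attenuation.
    """
    blend = np.zeros(image.shape, dtype=np.float32)
    tex_acc = np.zeros(image.shape, dtype=np.float32)
    for tex, soft in zip(textures, soft_masks):
        tex_acc = np.where(soft > blend, tex, tex_acc)
        blend = np.maximum(blend, soft)
    support = blend > 0
    tumor = np.full(image.shape, -1000.0, dtype=np.float32)
    parenchyma = np.full(image.shape, -1000.0, dtype=np.float32)
    tumor[support] = (blend * tex_acc + (1.0 - blend) * image.voxels)[support]
    parenchyma[support] = image.voxels[support]
    return image.like(tumor), image.like(parenchyma), blend


def simulate_tumor_scan(
    image: CTVolume,
    lung_mask: BinaryMask,
    bank: list[TumorTemplate],
    rng: np.random.Generator,
    *,
    n_tumors: int = 2,
    geom: ConeBeamGeometry | None = None,
    method: str = "projection",
    size_range_mm3: tuple[float, float] = (0.03, 70.0),
    min_tumor_mm3: float | None = None,
    edge_sigma_mm: float = 0.15,
    bilateral_sigmas: tuple[float, float] | None = (0.2, 60.0),
    cal: HUCalibration = HUCalibration(),
) -> tuple[CTVolume, BinaryMask, list[PlacedTumor]]:
    """Place ``n_tumors`` augmented tumors into a scan and re-image it.

    ``method='projection'`` runs the full forward-project / edit / FDK /
    bilateral chain; ``method='voxel'`` composites directly in the voxel
    domain (fast path used for large dataset assembly and as the oracle the
    projection route is validated against).
    """
    if not bank:
        raise ValueError("tumor bank is empty")
    if method not in ("projection", "voxel"):
        raise ValueError(f"unknown insertion method {method!r}")
    placed: list[PlacedTumor] = []
    textures: list[np.ndarray] = []
    softs: list[np.ndarray] = []
    for _ in range(n_tumors):
        template = bank[rng.integers(len(bank))]
        for _attempt in range(20):
            mask_small, affine = augment_tumor(template, rng, size_range_mm3)
            if min_tumor_mm3 is None or mask_small.volume_mm3 >= min_tumor_mm3:
                break
        if not np.isclose(mask_small.spacing_um, image.spacing_um):
            from ..core import resample_isotropic

            mask_small = resample_isotropic(mask_small, image.spacing_um)
        p = place_tumor(lung_mask, mask_small, placed, rng,
                        template_id=template.id, affine=affine)
        placed.append(p)
        tex, soft = retexture_tumor(
            p.mask, template.mean_hu, template.std_hu, rng, edge_sigma_mm
        )
        textures.append(tex)
        softs.append(soft)

    tumor_vol, parenchyma_vol, blend = compose_tumor_volumes(image, placed, textures, softs)
    labels = np.zeros(image.shape, dtype=np.uint8)
    for p in placed:
        labels |= p.mask.voxels
    label_mask = BinaryMask(labels, image.spacing_um, image.origin_mm.copy())

    if method == "voxel":
        composite = np.where(blend > 0, tumor_vol.voxels, image.voxels)
        return image.like(composite.astype(np.float32)), label_mask, placed

    if geom is None:
        geom = ConeBeamGeometry.for_volume(image)
    proj = forward_project(image, geom, cal)
    edited = insert_tumors_in_projections(proj, tumor_vol, parenchyma_vol, cal)
    recon = fdk_reconstruct(edited, image, cal)
    if bilateral_sigmas is not None:
        recon = bilateral_filter(recon, *bilateral_sigmas)
    return recon, label_mask, placed
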