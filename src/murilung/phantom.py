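"""Digital mouse-thorax phantom and synthetic tumor/prediction generators.

Every downstream stage (segmentation, tumor simulation, training, evaluation)
is exercisable on these objects without any real scan.  The thorax phantom
emulates the tissue classes of a gated mouse micro-CT in HU: background air
at -1000, lung parenchyma near -500 threaded with brighter vessel trees,
soft tissue in the 100-300 HU band, bone above 300 HU, and an air-filled
cradle trough touching the border air.  All geometric criteria are physical
(mm), so phantoms at different spacings describe the same animal.

What this phantom does *not* emulate: anatomically exact airway/lobe
anatomy, beam hardening, scatter, or respiratory motion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi

from .core import BinaryMask, CTVolume

__all__ = [
    "ThoraxPhantom",
    "TumorTemplate",
    "PhantomError",
    "generate_thorax",
    "generate_tumor_bank",
    "generate_prediction_map",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


class PhantomError(ValueError):
    """Infeasible phantom geometry or unsatisfiable construction request."""


@dataclass
class ThoraxPhantom:
    """A synthetic thorax image with construction-truth masks."""

    image: CTVolume
    lung_mask_truth: BinaryMask
    bone_mask: BinaryMask
    vessel_mask: BinaryMask
    body_mask: BinaryMask


@dataclass
class TumorTemplate:
    """One bank entry: a connected blobby mask plus target intensity stats."""

    mask: BinaryMask
    mean_hu: float
    std_hu: float
    id: int

    @property
    def volume_mm3(self) -> float:
        return self.mask.volume_mm3


# ------------------------------------------------------------------ thorax

_DEFAULT_HU = {
    "air": -1000.0,
    "lung": -500.0,
    "body": 180.0,
    "vessel": 75.0,
    "spine": 800.0,
    "rib": 500.0,
    "cradle": 120.0,
}


def generate_thorax(
    rng: np.random.Generator,
    spacing_um: float = 150.0,
    shape: tuple[int, int, int] = (200, 160, 160),
    *,
    noise_hu: float = 20.0,
    include_lungs: bool = True,
    lung_scale: float = 1.0,
    hu: dict | None = None,
) -> ThoraxPhantom:
    """Generate a mouse-thorax phantom with ground-truth masks.

    Parameters
    ----------
    rng : numpy Generator
        Drives lobe deformation, vessel trees, and additive noise.
    spacing_um : float
        Isotropic voxel size; 150 um keeps desk-scale runtime, 63 um works.
    shape : (nz, ny, nx)
        Grid shape; z is the cranio-caudal axis.
    noise_hu : float
        Sigma of additive Gaussian noise (0 gives the exact tissue values).
    include_lungs : bool
        When False a solid body is produced (lung-free control).
    lung_scale : float
        Uniform scale on the lobe semi-axes (lung volume scales ~cubically).
    """
    hu_map = dict(_DEFAULT_HU)
    if hu:
        hu_map.update(hu)
    s_mm = spacing_um / 1000.0
    nz, ny, nx = shape
    half = (np.array(shape, dtype=float) - 1) / 2.0 * s_mm
    z = (np.arange(nz) * s_mm - half[0])[:, None, None]
    y = (np.arange(ny) * s_mm - half[1])[None, :, None]
    x = (np.arange(nx) * s_mm - half[2])[None, None, :]

    # body: elliptical cylinder spanning z
    body_ay, body_ax, body_yc = 8.2, 9.2, 0.5
    if body_ay >= half[1] - 0.5 or body_ax >= half[2] - 0.5:
        raise PhantomError(
            f"body (semi-axes {body_ay}x{body_ax} mm) does not fit shape {shape} at {spacing_um} um"
        )
    body = ((y - body_yc) / body_ay) ** 2 + (x / body_ax) ** 2 <= 1.0
    body = np.broadcast_to(body, shape).copy()

    image = np.full(shape, hu_map["air"], dtype=np.float32)
    image[body] = hu_map["body"]

    # lungs: two deformed ellipsoidal lobes, separated at the midline
    lung = np.zeros(shape, dtype=bool)
    az, ay_l, ax_l = (6.3 * lung_scale, 3.8 * lung_scale, 3.0 * lung_scale)
    lobe_centers = [(0.5, -0.8, -4.2), (0.5, -0.8, 4.2)]
    if include_lungs:
        if az * 1.2 >= half[0]:
            raise PhantomError(f"lungs (half-length {az:.1f} mm) exceed z extent {half[0]:.1f} mm")
        for zc, yc, xc in lobe_centers:
            phases = rng.uniform(0, 2 * np.pi, size=3)
            quad = ((z - zc) / az) ** 2 + ((y - yc) / ay_l) ** 2 + ((x - xc) / ax_l) ** 2
            ripple = (
                0.12
                * np.sin(2.1 * (z - zc) / az + phases[0])
                * np.sin(1.7 * (y - yc) / ay_l + phases[1])
                * np.cos(1.9 * (x - xc) / ax_l + phases[2])
            )
            lung |= quad <= 1.0 + ripple
        lung &= body
        image[lung] = hu_map["lung"]

    # vessel trees: recursive random branching from each hilum, radius decay
    vessel = np.zeros(shape, dtype=bool)
    if include_lungs:
        for zc, yc, xc in lobe_centers:
            hilum = np.array([zc - 1.0, yc, np.sign(xc) * 1.6])
            _grow_tree(vessel, rng, hilum, np.array([0.3, 0.0, np.sign(xc) * 0.95]),
                       length=2.6, radius=0.38, depth=4, s_mm=s_mm, half=half)
        vessel &= lung
        image[vessel] = hu_map["vessel"]

    # bone: spine cylinder plus thin rib bands; never inside the lungs
    bone = ((y - 6.6) ** 2 + x**2) <= 1.3**2
    bone = np.broadcast_to(bone, shape).copy()
    rib_val = ((y - body_yc) / (body_ay * 0.90)) ** 2 + (x / (body_ax * 0.90)) ** 2
    rib_band = np.abs(rib_val - 1.0) < 0.055
    z_flat = z[:, 0, 0]
    rib_planes = np.zeros(nz, dtype=bool)
    for zr in np.arange(-half[0] + 2.0, half[0] - 2.0, 2.5):
        rib_planes |= np.abs(z_flat - zr) < 0.25
    ribs = rib_planes[:, None, None] & rib_band & body
    image[bone & body] = hu_map["spine"]
    image[ribs & ~bone] = hu_map["rib"]
    bone_mask = (bone | ribs) & body & ~lung
    image[lung] = np.where(vessel[lung], hu_map["vessel"], hu_map["lung"]).astype(np.float32)

    # cradle: a solid trough below the animal with air in between, reaching
    # the volume border along z so the cradle air joins the background air
    cradle_val = ((y - body_yc + 1.5) / (body_ay + 2.2)) ** 2 + (x / (body_ax + 1.1)) ** 2
    cradle = (cradle_val >= 1.0) & (cradle_val <= 1.16) & np.broadcast_to(y < -3.0, shape)
    cradle = cradle & ~body
    image[cradle] = hu_map["cradle"]

    if noise_hu > 0:
        image = image + rng.normal(0.0, noise_hu, size=shape).astype(np.float32)

    vol = CTVolume(image.astype(np.float32), spacing_um, -half)
    lung_mask = BinaryMask(lung.astype(np.uint8), spacing_um, -half)
    if include_lungs:
        v = lung_mask.volume_mm3
        if not (200.0 <= v <= 1200.0):
            raise PhantomError(f"generated lung volume {v:.0f} mm^3 outside [200, 1200]")
    return ThoraxPhantom(
        image=vol,
        lung_mask_truth=lung_mask,
        bone_mask=BinaryMask(bone_mask.astype(np.uint8), spacing_um, -half),
        vessel_mask=BinaryMask(vessel.astype(np.uint8), spacing_um, -half),
        body_mask=BinaryMask(body.astype(np.uint8), spacing_um, -half),
    )


def _grow_tree(canvas, rng, p0, direction, length, radius, depth, s_mm, half):
    """Rasterize one vessel segment as stacked spheres, then recurse."""
    direction = direction / np.linalg.norm(direction)
    p1 = p0 + direction * length
    n_steps = max(2, int(length / (0.5 * s_mm)))
    r_vox = max(1, int(round(radius / s_mm)))
    shape = canvas.shape
    for t in np.linspace(0.0, 1.0, n_steps):
        c = p0 + t * (p1 - p0)
        idx = np.round((c + half) / s_mm).astype(int)
        lo = np.maximum(idx - r_vox, 0)
        hi = np.minimum(idx + r_vox + 1, shape)
        if np.any(lo >= hi):
            continue
        zz, yy, xx = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        ball = (zz - idx[0]) ** 2 + (yy - idx[1]) ** 2 + (xx - idx[2]) ** 2 <= r_vox**2
        canvas[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] |= ball
    if depth <= 1:
        return
    n_children = 2
    for _ in range(n_children):
        # rotate the direction by a random branching angle
        perturb = rng.normal(0.0, 0.55, size=3)
        child_dir = direction + perturb
        _grow_tree(canvas, rng, p1, child_dir, length * 0.75, radius * 0.7,
                   depth - 1, s_mm, half)


# ------------------------------------------------------------------ tumor bank

def generate_tumor_bank(
    rng: np.random.Generator,
    n_templates: int = 7,
    size_range_mm3: tuple[float, float] = (0.03, 70.0),
    *,
    spacing_um: float = 150.0,
    mean_hu: float = 30.0,
    std_hu: float = 40.0,
) -> list[TumorTemplate]:
    """Generate a bank of connected, blobby tumor-template masks.

    Each template is the superlevel set (exact top-k voxels) of a sum of a few
    overlapping anisotropic Gaussians, giving irregular but single-component
    blobs whose volume matches a log-uniform draw from ``size_range_mm3`` to
    within one voxel volume.
    """
    if n_templates < 1:
        raise PhantomError("n_templates must be >= 1")
    lo, hi = size_range_mm3
    if not (0 < lo <= hi):
        raise PhantomError(f"bad size range {size_range_mm3}")
    voxvol = (spacing_um / 1000.0) ** 3
    if lo / voxvol < 1.0:
        raise PhantomError(
            f"size range lower bound {lo} mm^3 is below one voxel at {spacing_um} um"
        )
    bank = []
    for i in range(n_templates):
        target = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        mask = _metaball_mask(rng, target, spacing_um)
        bank.append(TumorTemplate(mask=mask, mean_hu=mean_hu, std_hu=std_hu, id=i))
    return bank


def _metaball_mask(rng, target_mm3, spacing_um, max_tries=50) -> BinaryMask:
    s_mm = spacing_um / 1000.0
    voxvol = s_mm**3
    k = max(1, int(round(target_mm3 / voxvol)))
    r_eq = (3.0 * target_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    half_mm = 2.2 * r_eq + 3 * s_mm
    n = 2 * int(np.ceil(half_mm / s_mm)) + 1
    coords = (np.arange(n) - (n - 1) / 2.0) * s_mm
    z = coords[:, None, None]
    y = coords[None, :, None]
    x = coords[None, None, :]
    for _ in range(max_tries):
        n_blobs = int(rng.integers(3, 7))
        field = np.zeros((n, n, n), dtype=np.float64)
        for _ in range(n_blobs):
            c = rng.uniform(-0.6 * r_eq, 0.6 * r_eq, size=3)
            sig = r_eq * rng.uniform(0.45, 0.9, size=3)
            field += np.exp(
                -(((z - c[0]) / sig[0]) ** 2 + ((y - c[1]) / sig[1]) ** 2 + ((x - c[2]) / sig[2]) ** 2)
            )
        flat = np.argpartition(field.ravel(), -k)[-k:]
        mask = np.zeros(field.size, dtype=np.uint8)
        mask[flat] = 1
        mask = mask.reshape(field.shape)
        _, n_comp = ndi.label(mask, structure=_STRUCT26)
        if n_comp == 1:
            return BinaryMask(mask, spacing_um)
    raise PhantomError(f"could not build a connected blob of {target_mm3} mm^3")


# ------------------------------------------------------------ prediction maps

def generate_prediction_map(
    labels,
    rng: np.random.Generator,
    *,
    n_false_pos: int = 0,
    miss_ids: tuple[int, ...] = (),
    blur_sigma_mm: float = 0.1,
    score_range: tuple[float, float] = (0.7, 1.0),
    lung_mask: BinaryMask | None = None,
    fp_volume_mm3: float = 0.4,
    max_trials: int = 2000,
) -> CTVolume:
    """Build a synthetic detector-output probability map with known errors.

    ``labels`` is a ``BinaryMask`` (components are labeled internally) or an
    integer label volume wrapped in a ``CTVolume``.  One blob is emitted per
    label id not in ``miss_ids``, overlapping that label; exactly
    ``n_false_pos`` spurious blobs are placed inside ``lung_mask`` away from
    every label (outside any near-hit radius), each above the minimum-volume
    filter.  The result is a float map in [0, 1] used to exercise detection
    post-processing with known (TP, FP, FN).
    """
    if isinstance(labels, BinaryMask):
        lab, n_lab = ndi.label(labels.voxels, structure=_STRUCT26)
        spacing_um = labels.spacing_um
        origin = labels.origin_mm
    else:
        lab = np.asarray(labels.voxels).astype(int)
        n_lab = int(lab.max())
        spacing_um = labels.spacing_um
        origin = labels.origin_mm
    s_mm = spacing_um / 1000.0
    voxvol = s_mm**3
    out = np.zeros(lab.shape, dtype=np.float32)

    centroids, radii = [], []
    for lid in range(1, n_lab + 1):
        where = np.argwhere(lab == lid)
        centroids.append(where.mean(axis=0))
        vol = len(where) * voxvol
        radii.append((3.0 * vol / (4.0 * np.pi)) ** (1.0 / 3.0))
        if lid in miss_ids:
            continue
        score = float(rng.uniform(*score_range))
        out[lab == lid] = np.maximum(out[lab == lid], score)

    if n_false_pos > 0:
        if lung_mask is None:
            allowed = np.ones(lab.shape, dtype=bool)
        else:
            allowed = lung_mask.as_bool()
        r_fp = (3.0 * fp_volume_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
        r_fp_vox = max(1, int(round(r_fp / s_mm)))
        cand = np.argwhere(allowed)
        if cand.size == 0:
            raise PhantomError("no lung space available for false positives")
        placed = 0
        fp_centers = []
        for _ in range(max_trials):
            if placed == n_false_pos:
                break
            c = cand[rng.integers(len(cand))]
            ok = True
            for ctr, r in zip(centroids, radii):
                # stay clear of the near-hit radius plus the blob's own extent
                if np.linalg.norm((c - ctr) * s_mm) < 1.6 * r + r_fp + 2 * s_mm:
                    ok = False
                    break
            for prev in fp_centers:
                if np.linalg.norm((c - prev) * s_mm) < 2.5 * r_fp:
                    ok = False
                    break
            if not ok:
                continue
            sphere = _sphere_at(lab.shape, c, r_fp_vox)
            if sphere.sum() * voxvol < 0.15:
                sphere = _sphere_at(lab.shape, c, r_fp_vox + 1)
            if not np.all(allowed[sphere]):
                continue
            out[sphere] = np.maximum(out[sphere], float(rng.uniform(*score_range)))
            fp_centers.append(c)
            placed += 1
        if placed < n_false_pos:
            raise PhantomError(
                f"placed only {placed}/{n_false_pos} false positives in the available lung space"
            )

    if blur_sigma_mm > 0:
        out = ndi.gaussian_filter(out, blur_sigma_mm / s_mm).astype(np.float32)
    np.clip(out, 0.0, 1.0, out=out)
    return CTVolume(out, spacing_um, origin)


def _sphere_at(shape, center, r_vox) -> np.ndarray:
    lo = np.maximum(np.asarray(center) - r_vox, 0)
    hi = np.minimum(np.asarray(center) + r_vox + 1, shape)
    mask = np.zeros(shape, dtype=bool)
    zz, yy, xx = np.ogrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    ball = (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - center[2]) ** 2 <= r_vox**2
    mask[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = ball
    return mask
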