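"""Tumor-template augmentation: random rotation, shear, scale, retexture.

Augmentation turns a small bank of template masks into an unlimited stream
of tumors spanning 0.03-70 mm^3.  The isotropic scale of each draw targets a
log-uniform volume law parameterized by its median (0.65 mm^3) and 90th
percentile (10 mm^3), clamped to the configured size range.  Transformed
masks lose their native texture, so placed tumors are re-filled with
Gaussian noise and composited through a Gaussian-smoothed soft mask to
avoid abrupt gray-value seams.
"""

from __future__ import annotations

import numpy as np
import scipy.ndimage as ndi

from ..core import BinaryMask
from ..phantom import TumorTemplate

__all__ = [
    "AugmentError",
    "draw_target_volume",
    "random_rotation",
    "random_shear",
    "apply_affine_to_mask",
    "augment_tumor",
    "retexture_tumor",
]


class AugmentError(RuntimeError):
    """Degenerate affine after repeated retries."""


def draw_target_volume(
    rng: np.random.Generator,
    size_range_mm3: tuple[float, float] = (0.03, 70.0),
    median_mm3: float = 0.65,
    q90_mm3: float = 10.0,
) -> float:
    """Log-uniform volume draw with the configured median and 90th percentile.

    The log-uniform bounds are solved from (median, q90): for log-volume
    uniform on [L, U], median = exp((L+U)/2) and q90 = exp(L + 0.9(U-L)).
    The draw is then clamped to ``size_range_mm3``.  When the configured
    median falls outside the size range (a custom narrow range), a plain
    log-uniform over the range is used instead.
    """
    lo_r, hi_r = size_range_mm3
    if not (0 < lo_r <= hi_r):
        raise ValueError(f"bad size range {size_range_mm3}")
    if lo_r < median_mm3 < q90_mm3:
        spread = (np.log(q90_mm3) - np.log(median_mm3)) / 0.4
        lo = np.log(median_mm3) - spread / 2.0
        v = float(np.exp(rng.uniform(lo, lo + spread)))
    else:
        v = float(np.exp(rng.uniform(np.log(lo_r), np.log(hi_r))))
    return float(np.clip(v, lo_r, hi_r))


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform SO(3) rotation matrix from a random unit quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
        ]
    )


def random_shear(rng: np.random.Generator, max_shear: float = 0.2) -> np.ndarray:
    """Identity plus independent off-diagonal shear terms in [-max, max]."""
    s = np.eye(3)
    for i in range(3):
        for j in range(3):
            if i != j:
                s[i, j] = rng.uniform(-max_shear, max_shear)
    return s


def apply_affine_to_mask(
    mask: BinaryMask, affine: np.ndarray, *, margin: int = 2,
    target_volume_mm3: float | None = None,
) -> BinaryMask:
    """Resample a mask through a 3x3 voxel-space affine.

    The transform is applied about the mask centroid; the output grid is
    sized to hold the transformed bounding box.  By default the interpolated
    field is re-binarized at 0.5; when ``target_volume_mm3`` is given, the
    threshold is instead chosen so the discrete volume matches the continuous
    transformed volume (the highest-valued voxels are kept), removing the
    systematic shrinkage a fixed 0.5 level set introduces on blobby masks.
    The identity affine returns a volume equal to the input within one voxel
    volume (interpolation only).
    """
    affine = np.asarray(affine, dtype=float)
    coords = np.argwhere(mask.as_bool())
    if coords.size == 0:
        raise ValueError("cannot transform an empty mask")
    center_in = coords.mean(axis=0)
    corners = np.array(
        [[z, y, x] for z in (coords[:, 0].min() - 0.5, coords[:, 0].max() + 0.5)
         for y in (coords[:, 1].min() - 0.5, coords[:, 1].max() + 0.5)
         for x in (coords[:, 2].min() - 0.5, coords[:, 2].max() + 0.5)]
    ) - center_in
    t_corners = corners @ affine.T
    half = np.abs(t_corners).max(axis=0) + margin
    out_shape = tuple(int(np.ceil(2 * h)) + 1 for h in half)
    center_out = (np.array(out_shape) - 1) / 2.0
    inv = np.linalg.inv(affine)
    offset = center_in - inv @ center_out
    field = ndi.affine_transform(
        mask.voxels.astype(np.float32), inv, offset=offset, output_shape=out_shape, order=1
    )
    if target_volume_mm3 is not None:
        k = max(1, int(round(target_volume_mm3 / mask.voxel_volume_mm3)))
        k = min(k, field.size)
        out = np.zeros(field.size, dtype=np.uint8)
        out[np.argpartition(field.ravel(), -k)[-k:]] = 1
        out = out.reshape(field.shape)
    else:
        out = (field >= 0.5).astype(np.uint8)
        if out.sum() == 0:  # degenerate sub-voxel target: keep the peak voxel
            out.flat[int(np.argmax(field))] = 1
    return BinaryMask(out, mask.spacing_um)


def augment_tumor(
    template: TumorTemplate,
    rng: np.random.Generator,
    size_range_mm3: tuple[float, float] = (0.03, 70.0),
    *,
    median_mm3: float = 0.65,
    q90_mm3: float = 10.0,
    max_shear: float = 0.2,
    max_attempts: int = 100,
) -> tuple[BinaryMask, np.ndarray]:
    """One augmented tumor: random rotation + shear + volume-targeting scale.

    Returns the transformed binary mask (template grid spacing) and the 3x3
    affine that produced it.  Retries internally on a degenerate affine
    (determinant <= 0) and raises :class:`AugmentError` after
    ``max_attempts``.
    """
    target = draw_target_volume(rng, size_range_mm3, median_mm3, q90_mm3)
    v0 = template.volume_mm3
    for _ in range(max_attempts):
        base = random_rotation(rng) @ random_shear(rng, max_shear)
        det = float(np.linalg.det(base))
        if det <= 1e-6:
            continue
        scale = (target / (v0 * det)) ** (1.0 / 3.0)
        affine = scale * base
        out = apply_affine_to_mask(template.mask, affine, target_volume_mm3=target)
        return out, affine
    raise AugmentError(f"no valid affine after {max_attempts} attempts")


def _smoothing_rms_gain(sigma_vox: float, shape: tuple[int, int, int]) -> float:
    """RMS attenuation of white noise under a Gaussian filter of this sigma."""
    if sigma_vox <= 0:
        return 1.0
    n = min(int(6 * sigma_vox) * 2 + 3, min(shape))
    impulse = np.zeros((n, n, n))
    impulse[n // 2, n // 2, n // 2] = 1.0
    kernel = ndi.gaussian_filter(impulse, sigma_vox)
    return float(np.sqrt((kernel**2).sum()))


def retexture_tumor(
    mask: BinaryMask,
    target_mean_hu: float,
    target_std_hu: float,
    rng: np.random.Generator,
    edge_sigma_mm: float = 0.15,
    *,
    interior_smooth_vox: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian retexture plus a smoothed soft mask for seamless compositing.

    The interior is filled with i.i.d. Gaussian noise, lightly smoothed; the
    pre-smoothing variance is inflated so the *post*-smoothing interior std
    matches ``target_std_hu``.  The binary mask is blurred with
    ``edge_sigma_mm`` into blend weights in [0, 1] (``edge_sigma_mm = 0``
    returns the binary mask itself).
    """
    if target_std_hu < 0:
        raise ValueError("target_std_hu must be >= 0")
    if mask.voxels.sum() == 0:
        raise ValueError("mask is empty")
    gain = _smoothing_rms_gain(interior_smooth_vox, mask.shape)
    noise = rng.normal(0.0, 1.0, size=mask.shape)
    if interior_smooth_vox > 0:
        noise = ndi.gaussian_filter(noise, interior_smooth_vox)
    texture = target_mean_hu + noise * (target_std_hu / gain)
    if edge_sigma_mm > 0:
        soft = ndi.gaussian_filter(mask.voxels.astype(np.float64), edge_sigma_mm / mask.spacing_mm)
        soft = np.clip(soft, 0.0, 1.0)
    else:
        soft = mask.voxels.astype(np.float64)
    return texture.astype(np.float32), soft.astype(np.float32)
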