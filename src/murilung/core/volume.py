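"""Core image containers and intensity/grid operations.

Axis convention (fixed package-wide): arrays are indexed ``(z, y, x)`` with
``z`` the axial (cranio-caudal / rotation) axis, ``y`` the dorso-ventral axis
and ``x`` the left-right axis.  Voxel indices are 0-based; the physical
position of voxel ``(i, j, k)`` is ``origin_mm + index * spacing_mm``
(voxel centers).  Physical quantities are always computed from the spacing,
never from raw voxel counts, so the same criteria apply at any resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

__all__ = [
    "CTVolume",
    "BinaryMask",
    "HUCalibration",
    "CalibrationError",
    "to_hounsfield",
    "from_hounsfield",
    "resample_isotropic",
]


class CalibrationError(ValueError):
    """Raised for invalid air/water calibration pairs or non-finite input."""


def _as_origin(origin_mm) -> np.ndarray:
    if origin_mm is None:
        return np.zeros(3, dtype=np.float64)
    origin = np.asarray(origin_mm, dtype=np.float64)
    if origin.shape != (3,):
        raise ValueError(f"origin_mm must be a 3-vector, got shape {origin.shape}")
    return origin


@dataclass
class CTVolume:
    """A 3D scalar grid in Hounsfield units on an isotropic voxel lattice.

    Parameters
    ----------
    voxels : ndarray, shape (nz, ny, nx)
        Intensities in HU (air -1000, water 0).
    spacing_um : float
        Isotropic voxel edge length in micrometres.
    origin_mm : array-like of 3 floats, optional
        Physical position (z, y, x) of voxel ``(0, 0, 0)`` in millimetres.
    """

    voxels: np.ndarray
    spacing_um: float
    origin_mm: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("CTVolume requires a 3D array")
        if not np.isfinite(self.spacing_um) or self.spacing_um <= 0:
            raise ValueError(f"spacing_um must be positive, got {self.spacing_um}")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("CTVolume voxels must all be finite")
        self.origin_mm = _as_origin(self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def spacing_mm(self) -> float:
        return self.spacing_um / 1000.0

    @property
    def voxel_volume_mm3(self) -> float:
        return self.spacing_mm**3

    def centered(self) -> "CTVolume":
        """Copy with the origin set so the grid center sits at world (0,0,0)."""
        half = (np.array(self.shape, dtype=np.float64) - 1) / 2.0 * self.spacing_mm
        return CTVolume(self.voxels.copy(), self.spacing_um, -half)

    def copy(self) -> "CTVolume":
        return CTVolume(self.voxels.copy(), self.spacing_um, self.origin_mm.copy())

    def like(self, voxels: np.ndarray) -> "CTVolume":
        """New volume with the same grid placement but different intensities."""
        return CTVolume(voxels, self.spacing_um, self.origin_mm.copy())


@dataclass
class BinaryMask:
    """A voxel-aligned {0,1} grid (lungs, tumors, detections)."""

    voxels: np.ndarray
    spacing_um: float
    origin_mm: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        arr = np.asarray(self.voxels)
        if arr.ndim != 3:
            raise ValueError("BinaryMask requires a 3D array")
        if arr.dtype != np.uint8:
            uniques = np.unique(arr)
            if not np.all(np.isin(uniques, (0, 1))):
                raise ValueError("BinaryMask values must be 0 or 1")
            arr = arr.astype(np.uint8)
        self.voxels = arr
        if not np.isfinite(self.spacing_um) or self.spacing_um <= 0:
            raise ValueError(f"spacing_um must be positive, got {self.spacing_um}")
        self.origin_mm = _as_origin(self.origin_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def spacing_mm(self) -> float:
        return self.spacing_um / 1000.0

    @property
    def voxel_volume_mm3(self) -> float:
        return self.spacing_mm**3

    @property
    def volume_mm3(self) -> float:
        return float(self.voxels.sum()) * self.voxel_volume_mm3

    def as_bool(self) -> np.ndarray:
        return self.voxels.astype(bool)

    def like(self, voxels: np.ndarray) -> "BinaryMask":
        return BinaryMask(np.asarray(voxels).astype(np.uint8), self.spacing_um, self.origin_mm.copy())

    def matches_grid(self, other) -> bool:
        return self.shape == other.shape and np.isclose(self.spacing_um, other.spacing_um)


@dataclass(frozen=True)
class HUCalibration:
    """Linear attenuation of water and air (1/mm) used by the HU rescale.

    The default (``mu_water=0.02``, ``mu_air=0.0``) is a convenient synthetic
    calibration; only the ratio structure matters for the affine HU map.
    """

    mu_water: float = 0.02
    mu_air: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.mu_water) and np.isfinite(self.mu_air)):
            raise CalibrationError("calibration values must be finite")
        if self.mu_air < 0 or self.mu_water <= self.mu_air:
            raise CalibrationError(
                f"require mu_water > mu_air >= 0, got water={self.mu_water}, air={self.mu_air}"
            )


def to_hounsfield(raw, cal: HUCalibration = HUCalibration(), *, spacing_um: float | None = None):
    """Convert raw attenuation (1/mm) to Hounsfield units.

    Applies ``X_HU = 1000 * ((X - mu_air) / (mu_water - mu_air) - 1)`` so that
    water maps to 0 HU and air to -1000 HU.

    ``raw`` may be a ``CTVolume`` (returned as a new ``CTVolume``), or a bare
    ndarray; for an ndarray, a ``CTVolume`` is returned when ``spacing_um`` is
    given, else an ndarray.
    """
    if isinstance(raw, CTVolume):
        hu = to_hounsfield(raw.voxels, cal)
        return CTVolume(hu, raw.spacing_um, raw.origin_mm.copy())
    arr = np.asarray(raw, dtype=np.float64)
    if not np.all(np.isfinite(arr)):
        raise CalibrationError("attenuation input contains non-finite values")
    hu = 1000.0 * ((arr - cal.mu_air) / (cal.mu_water - cal.mu_air) - 1.0)
    if spacing_um is not None:
        return CTVolume(hu, spacing_um)
    return hu


def from_hounsfield(hu, cal: HUCalibration = HUCalibration(), *, clamp: bool = True):
    """Inverse HU rescale: HU back to linear attenuation (1/mm).

    With ``clamp`` (default) attenuation is floored at zero, guarding against
    voxels below -1000 HU produced by noise or filtering.
    """
    if isinstance(hu, CTVolume):
        arr = hu.voxels
    else:
        arr = np.asarray(hu)
    mu = cal.mu_air + (np.asarray(arr, dtype=np.float64) / 1000.0 + 1.0) * (cal.mu_water - cal.mu_air)
    if clamp:
        np.maximum(mu, 0.0, out=mu)
    return mu


def _target_shape(shape, spacing_um: float, target_um: float) -> tuple[int, ...]:
    return tuple(int(round(n * spacing_um / target_um)) for n in shape)


def resample_isotropic(vol, target_um: float, *, is_mask: bool | None = None):
    """Resample a volume or mask to a new isotropic spacing.

    Images are interpolated trilinearly; masks are interpolated trilinearly and
    re-binarized at 0.5.  The output grid has ``round(n * spacing / target)``
    voxels per axis, preserving the physical extent to within half a voxel.
    """
    if target_um <= 0 or not np.isfinite(target_um):
        raise ValueError(f"target_um must be positive, got {target_um}")
    if is_mask is None:
        is_mask = isinstance(vol, BinaryMask)
    spacing_um = vol.spacing_um
    if np.isclose(target_um, spacing_um):
        return vol.like(vol.voxels.copy())
    out_shape = _target_shape(vol.shape, spacing_um, target_um)
    if any(n < 2 for n in out_shape):
        raise ValueError(
            f"target spacing {target_um} um collapses shape {vol.shape} to {out_shape}"
        )
    zoom = [o / n for o, n in zip(out_shape, vol.shape)]
    data = vol.voxels.astype(np.float32)
    out = ndi.zoom(data, zoom, order=1, mode="nearest", grid_mode=True)
    # grid_mode=True treats samples as cells, matching the extent-preserving
    # "resize" semantics; clip tiny overshoot from the spline prefilter-free path
    if is_mask:
        out = (out >= 0.5).astype(np.uint8)
        return BinaryMask(out, target_um, vol.origin_mm.copy())
    return CTVolume(out, target_um, vol.origin_mm.copy())
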