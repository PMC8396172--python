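"""Circular cone-beam acquisition geometry and projection stacks.

The source orbits the z (cranio-caudal) axis at radius ``source_object_mm``;
a flat detector sits ``source_detector_mm`` from the source, perpendicular
to the source-isocenter axis, with rows along z (v) and columns along the
rotation direction (u).  Projection values are line integrals of linear
attenuation (unitless attenuation-length).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ConeBeamGeometry", "ProjectionSet", "GeometryError"]


class GeometryError(ValueError):
    """Invalid geometry, or a geometry that does not cover the volume."""


@dataclass(frozen=True)
class ConeBeamGeometry:
    n_views: int = 360
    angular_range_deg: float = 360.0
    source_object_mm: float = 200.0
    source_detector_mm: float = 400.0
    detector_rows: int = 128
    detector_cols: int = 128
    detector_pitch_mm: float = 0.2

    def __post_init__(self) -> None:
        if not (self.source_detector_mm > self.source_object_mm > 0):
            raise GeometryError(
                f"require source_detector > source_object > 0, got "
                f"{self.source_detector_mm}, {self.source_object_mm}"
            )
        if self.n_views < 1:
            raise GeometryError("n_views must be >= 1")
        if self.detector_rows < 1 or self.detector_cols < 1 or self.detector_pitch_mm <= 0:
            raise GeometryError("detector must have positive extent")

    @property
    def magnification(self) -> float:
        return self.source_detector_mm / self.source_object_mm

    @property
    def angles_rad(self) -> np.ndarray:
        full = np.deg2rad(self.angular_range_deg)
        return np.arange(self.n_views) * full / self.n_views

    @property
    def iso_pitch_mm(self) -> float:
        """Detector pitch rescaled to the plane through the isocenter."""
        return self.detector_pitch_mm / self.magnification

    @classmethod
    def for_volume(
        cls,
        vol,
        n_views: int = 180,
        angular_range_deg: float = 360.0,
        source_object_mm: float = 200.0,
        source_detector_mm: float = 400.0,
        margin: float = 1.45,
    ) -> "ConeBeamGeometry":
        """Magnification-matched geometry whose detector covers the volume."""
        mag = source_detector_mm / source_object_mm
        pitch = vol.spacing_mm * mag
        nz, ny, nx = vol.shape
        # size the detector for the worst-case magnification of the volume's
        # bounding cylinder, with a small safety margin
        half_xy = max(ny, nx) / 2.0 * vol.spacing_mm * np.sqrt(2.0)
        half_z = nz / 2.0 * vol.spacing_mm
        if half_xy >= source_object_mm:
            raise GeometryError("volume too large for the source orbit radius")
        worst_mag = source_detector_mm / (source_object_mm - half_xy)
        cols = int(np.ceil(2.0 * half_xy * worst_mag / pitch * (margin / 1.4))) + 4
        rows = int(np.ceil(2.0 * half_z * worst_mag / pitch * (margin / 1.4))) + 4
        return cls(
            n_views=n_views,
            angular_range_deg=angular_range_deg,
            source_object_mm=source_object_mm,
            source_detector_mm=source_detector_mm,
            detector_rows=rows,
            detector_cols=cols,
            detector_pitch_mm=pitch,
        )

    def covers(self, vol) -> bool:
        """Whether every voxel of a centered volume projects onto the detector."""
        half_xy = max(vol.shape[1], vol.shape[2]) / 2.0 * vol.spacing_mm * np.sqrt(2.0)
        half_z = vol.shape[0] / 2.0 * vol.spacing_mm
        if half_xy >= self.source_object_mm:
            return False
        # worst-case magnification for the nearest point of the object
        worst_mag = self.source_detector_mm / (self.source_object_mm - half_xy)
        u_need = half_xy * worst_mag
        v_need = half_z * worst_mag
        return (
            u_need <= self.detector_cols / 2.0 * self.detector_pitch_mm
            and v_need <= self.detector_rows / 2.0 * self.detector_pitch_mm
        )


@dataclass
class ProjectionSet:
    """Stack of 2D line-integral views with their acquisition geometry."""

    views: np.ndarray  # (n_views, rows, cols) float32
    geometry: ConeBeamGeometry

    def __post_init__(self) -> None:
        self.views = np.asarray(self.views, dtype=np.float32)
        g = self.geometry
        expected = (g.n_views, g.detector_rows, g.detector_cols)
        if self.views.shape != expected:
            raise GeometryError(f"views shape {self.views.shape} != geometry {expected}")
        if not np.all(np.isfinite(self.views)):
            raise GeometryError("projection values must be finite")

    def copy(self) -> "ProjectionSet":
        return ProjectionSet(self.views.copy(), self.geometry)
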