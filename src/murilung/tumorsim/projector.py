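"""Ray-driven cone-beam forward projection and voxel-driven backprojection.

The forward projector samples each source-to-pixel ray at half-voxel steps
with trilinear interpolation (a Joseph-style line integral); the
backprojector interpolates filtered projections bilinearly at each voxel's
detector footprint with the FDK distance weight.  Both are linear operators
and are compiled with numba.  A pluggable backend hook lets an external
tomography engine substitute for these kernels.
"""

from __future__ import annotations

import numpy as np
from numba import njit, prange

from ..core import CTVolume, HUCalibration, from_hounsfield
from .geometry import ConeBeamGeometry, GeometryError, ProjectionSet

__all__ = ["forward_project", "forward_project_attenuation", "backproject_weighted"]


@njit(cache=True, fastmath=True)
def _trilinear(vol, fz, fy, fx):
    nz, ny, nx = vol.shape
    if fz < 0.0 or fy < 0.0 or fx < 0.0 or fz > nz - 1.0 or fy > ny - 1.0 or fx > nx - 1.0:
        return 0.0
    z0 = int(fz)
    y0 = int(fy)
    x0 = int(fx)
    z1 = min(z0 + 1, nz - 1)
    y1 = min(y0 + 1, ny - 1)
    x1 = min(x0 + 1, nx - 1)
    dz = fz - z0
    dy = fy - y0
    dx = fx - x0
    c00 = vol[z0, y0, x0] * (1 - dx) + vol[z0, y0, x1] * dx
    c01 = vol[z0, y1, x0] * (1 - dx) + vol[z0, y1, x1] * dx
    c10 = vol[z1, y0, x0] * (1 - dx) + vol[z1, y0, x1] * dx
    c11 = vol[z1, y1, x0] * (1 - dx) + vol[z1, y1, x1] * dx
    c0 = c00 * (1 - dy) + c01 * dy
    c1 = c10 * (1 - dy) + c11 * dy
    return c0 * (1 - dz) + c1 * dz


@njit(cache=True, fastmath=True, parallel=True)
def _forward_kernel(vol, spacing, origin_zyx, angles, sod, sdd, rows, cols, pitch, step, out):
    nz, ny, nx = vol.shape
    z0w, y0w, x0w = origin_zyx[0], origin_zyx[1], origin_zyx[2]
    # volume bounding sphere for ray clipping
    cz = z0w + (nz - 1) * spacing / 2.0
    cy = y0w + (ny - 1) * spacing / 2.0
    cx = x0w + (nx - 1) * spacing / 2.0
    rad = 0.5 * spacing * np.sqrt((nz - 1.0) ** 2 + (ny - 1.0) ** 2 + (nx - 1.0) ** 2) + spacing
    for ia in prange(angles.shape[0]):
        th = angles[ia]
        cs = np.cos(th)
        sn = np.sin(th)
        sx = sod * cs
        sy = sod * sn
        for r in range(rows):
            v = (r - (rows - 1) / 2.0) * pitch
            for c in range(cols):
                u = (c - (cols - 1) / 2.0) * pitch
                # pixel position: S + sdd*(-cs,-sn,0) + u*(-sn,cs,0) + v*(0,0,1)
                px = sx - sdd * cs - u * sn
                py = sy - sdd * sn + u * cs
                pz = v
                dx = px - sx
                dy = py - sy
                dz = pz - 0.0
                norm = np.sqrt(dx * dx + dy * dy + dz * dz)
                dx /= norm
                dy /= norm
                dz /= norm
                # clip against the bounding sphere
                ox = cx - sx
                oy = cy - sy
                oz = cz - 0.0
                tmid = ox * dx + oy * dy + oz * dz
                d2 = ox * ox + oy * oy + oz * oz - tmid * tmid
                if d2 >= rad * rad:
                    out[ia, r, c] = 0.0
                    continue
                half = np.sqrt(rad * rad - d2)
                t0 = tmid - half
                t1 = tmid + half
                acc = 0.0
                t = t0
                while t <= t1:
                    wx = sx + t * dx
                    wy = sy + t * dy
                    wz = t * dz
                    fz = (wz - z0w) / spacing
                    fy = (wy - y0w) / spacing
                    fx = (wx - x0w) / spacing
                    acc += _trilinear(vol, fz, fy, fx)
                    t += step
                out[ia, r, c] = acc * step


@njit(cache=True, fastmath=True, parallel=True)
def _backproject_kernel(filtered, spacing, origin_zyx, angles, sod, iso_pitch, out):
    n_views, rows, cols = filtered.shape
    nz, ny, nx = out.shape
    z0w, y0w, x0w = origin_zyx[0], origin_zyx[1], origin_zyx[2]
    for iz in prange(nz):
        wz = z0w + iz * spacing
        for iy in range(ny):
            wy = y0w + iy * spacing
            for ix in range(nx):
                wx = x0w + ix * spacing
                acc = 0.0
                for ia in range(n_views):
                    th = angles[ia]
                    cs = np.cos(th)
                    sn = np.sin(th)
                    big_u = sod - (wx * cs + wy * sn)
                    if big_u <= 1e-6:
                        continue
                    ratio = sod / big_u
                    u_iso = (-wx * sn + wy * cs) * ratio
                    v_iso = wz * ratio
                    fc = u_iso / iso_pitch + (cols - 1) / 2.0
                    fr = v_iso / iso_pitch + (rows - 1) / 2.0
                    if fc < 0.0 or fr < 0.0 or fc > cols - 1.0 or fr > rows - 1.0:
                        continue
                    r0 = int(fr)
                    c0 = int(fc)
                    r1 = min(r0 + 1, rows - 1)
                    c1 = min(c0 + 1, cols - 1)
                    dr = fr - r0
                    dc = fc - c0
                    val = (
                        filtered[ia, r0, c0] * (1 - dr) * (1 - dc)
                        + filtered[ia, r0, c1] * (1 - dr) * dc
                        + filtered[ia, r1, c0] * dr * (1 - dc)
                        + filtered[ia, r1, c1] * dr * dc
                    )
                    acc += ratio * ratio * val
                out[iz, iy, ix] = acc


def forward_project_attenuation(mu: np.ndarray, vol_like: CTVolume, geom: ConeBeamGeometry,
                                *, check_coverage: bool = True) -> ProjectionSet:
    """Forward project a linear-attenuation volume (1/mm) on a volume's grid."""
    if check_coverage and not geom.covers(vol_like):
        raise GeometryError("detector does not cover the volume cone; enlarge the detector")
    vol_c = vol_like.centered()
    step = 0.5 * vol_like.spacing_mm
    out = np.zeros((geom.n_views, geom.detector_rows, geom.detector_cols), dtype=np.float64)
    _forward_kernel(
        np.ascontiguousarray(mu, dtype=np.float64),
        vol_like.spacing_mm,
        np.asarray(vol_c.origin_mm, dtype=np.float64),
        geom.angles_rad,
        geom.source_object_mm,
        geom.source_detector_mm,
        geom.detector_rows,
        geom.detector_cols,
        geom.detector_pitch_mm,
        step,
        out,
    )
    return ProjectionSet(out.astype(np.float32), geom)


def forward_project(vol: CTVolume, geom: ConeBeamGeometry,
                    cal: HUCalibration = HUCalibration()) -> ProjectionSet:
    """Line integrals of a HU volume (converted to attenuation internally).

    The volume is treated as centered at the isocenter.  Linear in the
    underlying attenuation.
    """
    mu = from_hounsfield(vol.voxels, cal)
    return forward_project_attenuation(mu, vol, geom)


def backproject_weighted(filtered: np.ndarray, geom: ConeBeamGeometry,
                         out_vol: CTVolume) -> np.ndarray:
    """FDK-weighted backprojection of filtered views onto a centered grid."""
    centered = out_vol.centered()
    out = np.zeros(out_vol.shape, dtype=np.float64)
    _backproject_kernel(
        np.ascontiguousarray(filtered, dtype=np.float64),
        out_vol.spacing_mm,
        np.asarray(centered.origin_mm, dtype=np.float64),
        geom.angles_rad,
        geom.source_object_mm,
        geom.iso_pitch_mm,
        out,
    )
    return out
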