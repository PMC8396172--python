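"""Feldkamp (FDK) filtered backprojection for circular cone-beam data.

Steps: cosine (distance) weighting of each view, row-wise ramp filtering
(Ram-Lak kernel, optional Hann apodization), and distance-weighted
backprojection.  Output is returned in HU via the air/water rescale.
"""

from __future__ import annotations

import warnings

import numpy as np

from ..core import CTVolume, HUCalibration, to_hounsfield
from .geometry import ConeBeamGeometry, ProjectionSet
from .projector import backproject_weighted

__all__ = ["fdk_reconstruct", "ramp_kernel"]


def ramp_kernel(n: int, du: float) -> np.ndarray:
    """Band-limited Ram-Lak kernel sampled at detector pitch ``du``.

    h[0] = 1/(4 du^2), h[n] = -1/(pi n du)^2 for odd n, 0 for even n.
    """
    idx = np.arange(-(n - 1), n)
    h = np.zeros(idx.shape, dtype=np.float64)
    h[idx == 0] = 1.0 / (4.0 * du**2)
    odd = idx % 2 != 0
    h[odd] = -1.0 / (np.pi * idx[odd] * du) ** 2
    return h


def _filter_views(views: np.ndarray, geom: ConeBeamGeometry, window: str) -> np.ndarray:
    n_views, rows, cols = views.shape
    du = geom.iso_pitch_mm
    sod = geom.source_object_mm

    u = (np.arange(cols) - (cols - 1) / 2.0) * du
    v = (np.arange(rows) - (rows - 1) / 2.0) * du
    cosw = sod / np.sqrt(sod**2 + u[None, :] ** 2 + v[:, None] ** 2)
    weighted = views * cosw[None, :, :]

    h = ramp_kernel(cols, du)
    nfft = int(2 ** np.ceil(np.log2(cols + h.size - 1)))
    H = np.fft.rfft(h, nfft)
    if window == "hann":
        freqs = np.arange(H.size)
        H = H * (0.5 + 0.5 * np.cos(np.pi * freqs / max(H.size - 1, 1)))
    elif window != "ramlak":
        raise ValueError(f"unknown filter window {window!r}")
    spec = np.fft.rfft(weighted, nfft, axis=2)
    full = np.fft.irfft(spec * H[None, None, :], nfft, axis=2)
    # 'same' part of the full convolution, times du for the integral step
    return full[:, :, cols - 1 : 2 * cols - 1] * du


def fdk_reconstruct(
    proj: ProjectionSet,
    out_grid,
    cal: HUCalibration = HUCalibration(),
    *,
    window: str = "ramlak",
    min_views_per_extent: float = 0.5,
) -> CTVolume:
    """Reconstruct a HU volume from cone-beam projections.

    ``out_grid`` is a template ``CTVolume`` (its shape/spacing/origin are
    used) or a ``(shape, spacing_um)`` pair.  Too few views for the grid
    triggers a warning, not an error.
    """
    if isinstance(out_grid, CTVolume):
        template = out_grid
    else:
        shape, spacing_um = out_grid
        template = CTVolume(np.zeros(shape, dtype=np.float32), spacing_um).centered()
    geom = proj.geometry
    if geom.n_views < min_views_per_extent * max(template.shape):
        warnings.warn(
            f"{geom.n_views} views is few for a {max(template.shape)}-voxel grid; "
            "expect streak artifacts",
            stacklevel=2,
        )
    filtered = _filter_views(np.asarray(proj.views, dtype=np.float64), geom, window)
    accum = backproject_weighted(filtered, geom, template)
    dbeta = np.deg2rad(geom.angular_range_deg) / geom.n_views
    mu = accum * dbeta / 2.0
    hu = to_hounsfield(mu, cal)
    return CTVolume(hu.astype(np.float32), template.spacing_um, template.origin_mm.copy())
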