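"""Stitched sliding-window inference over a full volume."""

from __future__ import annotations

import numpy as np

from ..core import CTVolume, get_logger
from .vnet import VNet

__all__ = ["sliding_window_predict", "patch_origins"]

_log = get_logger("detector")


def patch_origins(dim: int, patch: int, stride: int) -> list[int]:
    """Origins covering [0, dim) with the final patch clamped to the edge."""
    if dim <= patch:
        return [0]
    origins = list(range(0, dim - patch + 1, stride))
    if origins[-1] != dim - patch:
        origins.append(dim - patch)
    return origins


def sliding_window_predict(
    model: VNet,
    vol: CTVolume,
    patch_size: int,
    stride: int = 12,
    *,
    normalization_divisor: float = 1000.0,
    batch_size: int = 4,
) -> CTVolume:
    """Average overlapping patch predictions into one probability volume.

    Patches of ``patch_size`` are extracted with the given stride in each
    direction (edge patches clamped to the volume); every voxel's output is
    the mean of all patch predictions covering it, so values stay in [0, 1].
    A volume smaller than the patch is padded with air and processed as a
    single patch.
    """
    data = vol.voxels.astype(np.float32) / normalization_divisor
    shape = np.array(data.shape)
    pad = np.maximum(patch_size - shape, 0)
    if np.any(pad > 0):
        _log.warning("volume %s smaller than patch %d; padding with air", tuple(shape), patch_size)
        data = np.pad(
            data,
            [(0, int(p)) for p in pad],
            mode="constant",
            constant_values=-1.0,
        )
    acc = np.zeros(data.shape, dtype=np.float64)
    cnt = np.zeros(data.shape, dtype=np.int32)
    origins = [
        (z, y, x)
        for z in patch_origins(data.shape[0], patch_size, stride)
        for y in patch_origins(data.shape[1], patch_size, stride)
        for x in patch_origins(data.shape[2], patch_size, stride)
    ]
    for start in range(0, len(origins), batch_size):
        chunk = origins[start : start + batch_size]
        batch = np.stack(
            [data[z : z + patch_size, y : y + patch_size, x : x + patch_size] for z, y, x in chunk]
        )[:, None]
        pred = model.forward(batch, training=False)
        for (z, y, x), p in zip(chunk, pred[:, 0]):
            acc[z : z + patch_size, y : y + patch_size, x : x + patch_size] += p
            cnt[z : z + patch_size, y : y + patch_size, x : x + patch_size] += 1
    out = (acc / cnt)[: vol.shape[0], : vol.shape[1], : vol.shape[2]]
    return CTVolume(out.astype(np.float32), vol.spacing_um, vol.origin_mm.copy())
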