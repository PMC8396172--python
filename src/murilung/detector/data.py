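"""Training data plumbing: folds, patch sampling, and the Dice metric."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..core import BinaryMask, CTVolume, get_logger

__all__ = ["TrainConfig", "FoldSplit", "make_folds", "sample_patch", "dice_coefficient"]

_log = get_logger("detector")

STRATEGIES = ("sim_only", "real_only", "combined", "transfer")


@dataclass
class TrainConfig:
    """Training hyperparameters (full-scale defaults; shrink for desk runs)."""

    strategy: str = "sim_only"
    k_folds: int = 5
    epochs: int = 5000
    lr0: float = 0.01
    beta1: float = 0.9  # Adam's momentum term
    batch_size: int = 3
    lr_decay: float = 0.9
    lr_decay_every: int = 100
    patch_size: int = 96
    p_tumor_patch: float = 0.8
    normalization_divisor: float = 1000.0
    resample_um: float = 100.0
    coronal_flip_prob: float = 0.5
    transfer_epochs: int | None = None

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"strategy must be one of {STRATEGIES}")
        if not (0.0 <= self.p_tumor_patch <= 1.0):
            raise ValueError("p_tumor_patch must be in [0, 1]")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.lr0 <= 0:
            raise ValueError("lr0 must be positive")


@dataclass
class FoldSplit:
    """Per-fold train/test id lists; test sets partition the scan ids."""

    folds: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.folds)

    def __iter__(self):
        return iter(self.folds)


def make_folds(scan_ids: list, k: int = 5, rng: np.random.Generator | None = None) -> FoldSplit:
    """Balanced K-fold partition so every scan is tested exactly once."""
    ids = list(scan_ids)
    if len(ids) < k:
        raise ValueError(f"need at least k={k} scans, got {len(ids)}")
    if rng is None:
        rng = np.random.default_rng(0)
    perm = list(rng.permutation(len(ids)))
    test_sets = [sorted(ids[i] for i in chunk) for chunk in np.array_split(perm, k)]
    folds = [
        {"test": test, "train": sorted(set(ids) - set(test))}
        for test in test_sets
    ]
    return FoldSplit(folds)


def sample_patch(
    image: CTVolume,
    label: BinaryMask,
    cfg: TrainConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One training patch pair, normalized and optionally flipped.

    With probability ``p_tumor_patch`` the patch is drawn so it contains all
    or part of a tumor (a random label voxel with a uniformly chosen
    containing window, clamped at borders); otherwise the origin is uniform.
    Intensities are divided by 1000; a left-right (coronal-plane) mirror is
    applied to both patch and label with probability 0.5.
    """
    ps = cfg.patch_size
    shape = np.array(image.shape)
    if np.any(shape < ps):
        raise ValueError(f"volume {tuple(shape)} smaller than patch size {ps}")
    tumor_vox = np.argwhere(label.as_bool())
    want_tumor = rng.random() < cfg.p_tumor_patch
    if want_tumor and len(tumor_vox) == 0:
        _log.warning("tumor patch requested on an empty label map; sampling at random")
        want_tumor = False
    if want_tumor:
        target = tumor_vox[rng.integers(len(tumor_vox))]
        lo = np.maximum(target - ps + 1, 0)
        hi = np.minimum(target, shape - ps)
        hi = np.maximum(hi, lo)
        origin = np.array([rng.integers(l, h + 1) for l, h in zip(lo, hi)])
    else:
        origin = np.array([rng.integers(0, n - ps + 1) for n in shape])
    sl = tuple(slice(o, o + ps) for o in origin)
    patch = image.voxels[sl].astype(np.float32) / cfg.normalization_divisor
    lab = label.voxels[sl].astype(np.float32)
    if rng.random() < cfg.coronal_flip_prob:
        patch = patch[:, :, ::-1].copy()
        lab = lab[:, :, ::-1].copy()
    return patch, lab


def dice_coefficient(pred: np.ndarray, target: np.ndarray) -> float:
    """Dice overlap ``2|P.T| / (|P| + |T|)``.

    For binary inputs this is the set-overlap Dice; for a soft prediction the
    intersection is the sum of products.  Both-empty inputs are defined as
    perfect agreement (D = 1).
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {target.shape}")
    denom = pred.sum() + target.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (pred * target).sum() / denom)
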