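"""V-Net-style volumetric encoder/decoder for nodule probability maps.

The network halves the resolution once per stage in the encoder (2x2x2
convolutions, stride 2) and restores it with transposed convolutions in the
decoder.  Every stage is a block of 5x5x5 convolutions, each followed by
batch normalization, PReLU, and light dropout, with a residual connection
around the block; encoder features re-enter the decoder at matching
resolution via channel concatenation.  A final 1x1x1 convolution and
sigmoid produce a per-voxel probability in [0, 1] at the input resolution.
The full-size configuration (5 stages, channels 16..256) mirrors the
published architecture; the defaults here are exposed so a toy instance
trains on a desk CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .layers import Adam, BatchNorm3d, Conv3d, DownConv, Dropout, PReLU, Sigmoid, UpConv

__all__ = ["NetworkSpec", "VNet", "build_network"]


@dataclass(frozen=True)
class NetworkSpec:
    n_stages: int = 5
    channels: tuple[int, ...] = (8, 16, 32, 64, 128)
    convs_per_stage: tuple[int, ...] = (1, 2, 3, 3, 3)
    conv_kernel: int = 5
    dropout_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_stages < 1:
            raise ValueError("n_stages must be >= 1")
        if len(self.channels) != self.n_stages or len(self.convs_per_stage) != self.n_stages:
            raise ValueError("channels and convs_per_stage must have n_stages entries")
        if any(n < 1 or n > 3 for n in self.convs_per_stage):
            raise ValueError("stages hold 1 to 3 convolution layers")
        if self.channels[0] % 1 != 0 or any(c < 1 for c in self.channels):
            raise ValueError("channel counts must be positive")

    def validate_patch(self, patch: int) -> None:
        if patch % 2 ** (self.n_stages - 1) != 0:
            raise ValueError(
                f"patch size {patch} not divisible by 2^{self.n_stages - 1}"
            )


class _ConvBlock:
    """n convolutions (each conv+BN+PReLU+dropout) with a residual add.

    When the residual input has fewer channels than the block output, the
    input channels are tiled to match (the single-channel image is repeated
    across feature maps, as in the original architecture).
    """

    def __init__(self, cin, cout, n_convs, k, dropout, rng):
        if cout % cin != 0:
            raise ValueError(f"residual tiling needs cout % cin == 0 ({cin} -> {cout})")
        self.reps = cout // cin
        self.layers = []
        c = cin
        for _ in range(n_convs):
            self.layers.extend(
                [Conv3d(c, cout, k, rng), BatchNorm3d(cout), PReLU(cout), Dropout(dropout, rng)]
            )
            c = cout

    def forward(self, x, training):
        y = x
        for layer in self.layers:
            y = layer.forward(y, training)
        if self.reps > 1:
            res = np.repeat(x, self.reps, axis=1)
        else:
            res = x
        self._tile_shape = x.shape
        return y + res

    def backward(self, g):
        gres = g
        gy = g
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        if self.reps > 1:
            n, c, d, h, w = self._tile_shape
            gres = gres.reshape(n, c, self.reps, d, h, w).sum(axis=2)
        return gy + gres


class VNet:
    """Encoder/decoder model; ``forward``/``backward`` mirror each other."""

    def __init__(self, spec: NetworkSpec) -> None:
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        ch = spec.channels
        k = spec.conv_kernel
        dr = spec.dropout_rate
        s = spec.n_stages

        self.enc_blocks = []
        self.down = []
        for i in range(s):
            cin = 1 if i == 0 else ch[i]
            self.enc_blocks.append(_ConvBlock(cin, ch[i], spec.convs_per_stage[i], k, dr, rng))
            if i < s - 1:
                self.down.append(
                    [DownConv(ch[i], ch[i + 1], rng), BatchNorm3d(ch[i + 1]),
                     PReLU(ch[i + 1]), Dropout(dr, rng)]
                )
        self.up = []
        self.dec_blocks = []
        for i in range(s - 2, -1, -1):
            self.up.append(
                [UpConv(ch[i + 1], ch[i], rng), BatchNorm3d(ch[i]), PReLU(ch[i]), Dropout(dr, rng)]
            )
            self.dec_blocks.append(
                _DecoderBlock(ch[i], spec.convs_per_stage[i], k, dr, rng)
            )
        self.final = Conv3d(ch[0], 1, 1, rng)
        self.sigmoid = Sigmoid()

    # ---- plumbing

    def layers(self):
        for block in self.enc_blocks:
            yield from block.layers
        for group in self.down:
            yield from group
        for group in self.up:
            yield from group
        for block in self.dec_blocks:
            yield from block.layers
        yield self.final
        yield self.sigmoid

    @property
    def n_parameters(self) -> int:
        return sum(l.n_parameters for l in self.layers() if hasattr(l, "n_parameters"))

    def zero_grads(self) -> None:
        for l in self.layers():
            if l.params:
                l.zero_grads()

    def make_optimizer(self, lr: float = 0.01, beta1: float = 0.9) -> Adam:
        return Adam(list(self.layers()), lr=lr, beta1=beta1)

    def set_dropout_rng(self, rng: np.random.Generator) -> None:
        for l in self.layers():
            if isinstance(l, Dropout):
                l.rng = rng

    def get_weights(self) -> list[np.ndarray]:
        out = []
        for l in self.layers():
            for k in sorted(l.params):
                out.append(l.params[k].copy())
            if isinstance(l, BatchNorm3d):
                out.append(l.running_mean.copy())
                out.append(l.running_var.copy())
        return out

    def set_weights(self, weights: list[np.ndarray]) -> None:
        it = iter(weights)
        for l in self.layers():
            for k in sorted(l.params):
                l.params[k][...] = next(it)
            if isinstance(l, BatchNorm3d):
                l.running_mean[...] = next(it)
                l.running_var[...] = next(it)

    # ---- forward / backward

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if x.ndim != 5 or x.shape[1] != 1:
            raise ValueError(f"expected (N, 1, D, H, W), got {x.shape}")
        self.spec.validate_patch(x.shape[2])
        skips = []
        y = x.astype(np.float32)
        for i, block in enumerate(self.enc_blocks):
            y = block.forward(y, training)
            if i < len(self.down):
                skips.append(y)
                for layer in self.down[i]:
                    y = layer.forward(y, training)
        for group, block in zip(self.up, self.dec_blocks):
            for layer in group:
                y = layer.forward(y, training)
            y = block.forward(y, skips.pop(), training)
        y = self.final.forward(y, training)
        return self.sigmoid.forward(y)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = self.sigmoid.backward(gout)
        g = self.final.backward(g)
        gskips = []
        for group, block in zip(reversed(self.up), reversed(self.dec_blocks)):
            g, gskip = block.backward(g)
            gskips.append(gskip)
            for layer in reversed(group):
                g = layer.backward(g)
        for i in range(len(self.enc_blocks) - 1, -1, -1):
            if i < len(self.down):
                for layer in reversed(self.down[i]):
                    g = layer.backward(g)
                g = g + gskips.pop()  # deepest skip grad first
            g = self.enc_blocks[i].backward(g)
        return g


class _DecoderBlock:
    """Concat(skip, upsampled) -> conv block; residual from the upsampled path."""

    def __init__(self, c, n_convs, k, dropout, rng):
        self.layers = []
        cin = 2 * c
        for _ in range(n_convs):
            self.layers.extend(
                [Conv3d(cin, c, k, rng), BatchNorm3d(c), PReLU(c), Dropout(dropout, rng)]
            )
            cin = c

    def forward(self, up, skip, training):
        self._c = up.shape[1]
        y = np.concatenate([up, skip], axis=1)
        for layer in self.layers:
            y = layer.forward(y, training)
        return y + up

    def backward(self, g):
        gy = g
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        gup = gy[:, : self._c] + g
        gskip = gy[:, self._c :]
        return gup, gskip


def build_network(spec: NetworkSpec) -> tuple[VNet, int]:
    """Construct the model and report its exact trainable-parameter count."""
    model = VNet(spec)
    return model, model.n_parameters
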