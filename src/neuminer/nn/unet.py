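"""A plain 3D U-Net with instance normalization and two supervision heads.

Symmetric encoder-decoder with skip connections: each level applies two
3x3x3 convolutions, each followed by instance normalization and a leaky
ReLU; 2x max pooling between encoder levels and nearest-neighbor upsampling
(plus a 3x3x3 channel-reducing convolution) between decoder levels. Two
1x1x1 heads emit 2-channel (background/foreground) logit maps for deep
supervision: the final decoder block at full resolution, and the block
before it at half resolution (for a 2-level network that is the
bottleneck). Forward and backward passes are explicit numpy; there is no
autograd.
"""

from __future__ import annotations

import numpy as np

from .layers import (Conv3d, InstanceNorm3d, LeakyReLU, MaxPool3d, Param,
                     Upsample3d)

__all__ = ["UNet3D", "build_network"]


class _ConvBlock:
    """Conv-IN-LReLU twice."""

    def __init__(self, cin, cout, rng, name):
        self.layers = [
            Conv3d(cin, cout, 3, rng, f"{name}.conv0"),
            InstanceNorm3d(cout, name=f"{name}.in0"),
            LeakyReLU(),
            Conv3d(cout, cout, 3, rng, f"{name}.conv1"),
            InstanceNorm3d(cout, name=f"{name}.in1"),
            LeakyReLU(),
        ]

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


class UNet3D:
    """See module docstring. ``forward`` returns (final_logits, aux_logits)."""

    def __init__(self, levels: int = 4, base_channels: int = 16,
                 in_channels: int = 1, n_classes: int = 2,
                 seed: int | None = 0):
        if levels < 2:
            raise ValueError("need at least 2 resolution levels")
        rng = np.random.default_rng(seed)
        self.levels = levels
        self.channels = [base_channels * 2**i for i in range(levels)]
        ch = self.channels
        self.enc = []
        cin = in_channels
        for i in range(levels):
            self.enc.append(_ConvBlock(cin, ch[i], rng, f"enc{i}"))
            cin = ch[i]
        self.pool = [MaxPool3d() for _ in range(levels - 1)]
        self.up = [Upsample3d() for _ in range(levels - 1)]
        # 1x1x1 channel reduction after nearest upsampling; the decoder
        # block's 3x3x3 convs do the spatial smoothing
        self.upconv = [Conv3d(ch[i + 1], ch[i], 1, rng, f"upconv{i}")
                       for i in range(levels - 1)]
        self.dec = [_ConvBlock(2 * ch[i], ch[i], rng, f"dec{i}")
                    for i in range(levels - 1)]
        self.head_final = Conv3d(ch[0], n_classes, 1, rng, "head_final")
        aux_ch = ch[1]
        self.head_aux = Conv3d(aux_ch, n_classes, 1, rng, "head_aux")
        self._cache = None

    # ------------------------------------------------------------------
    def _min_size(self) -> int:
        return 2 ** (self.levels - 1)

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        x = np.asarray(x)
        if not np.issubdtype(x.dtype, np.floating):
            x = x.astype(np.float32)
        if x.ndim != 5:
            raise ValueError("input must be (B, C, Z, Y, X)")
        m = self._min_size()
        if any(s % m for s in x.shape[2:]):
            raise ValueError(
                f"spatial dims {x.shape[2:]} must be multiples of {m}")
        skips = []
        for i in range(self.levels - 1):
            x = self.enc[i].forward(x)
            skips.append(x)
            x = self.pool[i].forward(x)
        x = self.enc[-1].forward(x)
        bottleneck = x
        dec_out = {}
        for i in reversed(range(self.levels - 1)):
            x = self.upconv[i].forward(self.up[i].forward(x))
            x = np.concatenate([skips[i], x], axis=1)
            x = self.dec[i].forward(x)
            dec_out[i] = x
        final = self.head_final.forward(dec_out[0])
        aux_src = dec_out[1] if self.levels >= 3 else bottleneck
        aux = self.head_aux.forward(aux_src)
        self._cache = {"skip_channels": [s.shape[1] for s in skips]}
        return final, aux

    __call__ = forward

    def backward(self, g_final: np.ndarray, g_aux: np.ndarray) -> None:
        skip_ch = self._cache["skip_channels"]
        g = self.head_final.backward(np.asarray(g_final))
        g_aux_src = self.head_aux.backward(np.asarray(g_aux))
        skip_grads = {}
        for i in range(self.levels - 1):  # decoder blocks, full res first
            if i == 1 and self.levels >= 3:
                g = g + g_aux_src
            g = self.dec[i].backward(g)
            skip_grads[i] = g[:, : skip_ch[i]]
            g = self.upconv[i].backward(g[:, skip_ch[i]:])
            g = self.up[i].backward(g)
        if self.levels == 2:
            g = g + g_aux_src
        g = self.enc[-1].backward(g)
        for i in reversed(range(self.levels - 1)):
            g = self.pool[i].backward(g)
            g = g + skip_grads[i]
            g = self.enc[i].backward(g)

    # ------------------------------------------------------------------
    def params(self) -> list[Param]:
        out = []
        for block in self.enc + self.dec:
            out.extend(block.params())
        for conv in self.upconv:
            out.extend(conv.params())
        out.extend(self.head_final.params())
        out.extend(self.head_aux.params())
        return out

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.params()))

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.value.copy() for p in self.params()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for p in self.params():
            if p.name not in state:
                raise KeyError(f"missing parameter {p.name}")
            if state[p.name].shape != p.value.shape:
                raise ValueError(f"shape mismatch for {p.name}")
            p.value[...] = state[p.name]


def build_network(levels: int = 4, base_channels: int = 16,
                  in_channels: int = 1, n_classes: int = 2,
                  seed: int | None = 0) -> UNet3D:
    """Construct a :class:`UNet3D`; thin named constructor."""
    return UNet3D(levels=levels, base_channels=base_channels,
                  in_channels=in_channels, n_classes=n_classes, seed=seed)
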