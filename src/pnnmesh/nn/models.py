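"""U-Net generator and PatchGAN discriminator.

The generator is an encoder-decoder with skip connections: each encoder
level halves the spatial resolution with a 4x4 stride-2 convolution, each
decoder level doubles it with a 4x4 stride-2 transposed convolution and
concatenates the same-resolution encoder features.  Channel counts double
per level from ``base_channels`` up to ``channel_cap``.  The final layer
maps to one channel through tanh, so outputs live in [-1, 1] like the
normalised inputs.

The discriminator is a PatchGAN: a fully convolutional stack whose output
is a grid of logits, each judging one receptive-field-sized image fragment
("fragment diameter").  Judging fragments rather than the whole image
makes it a texture/style critic that assumes pixels further apart than one
fragment are independent.
"""

from __future__ import annotations

import numpy as np

from .layers import (
    Conv2d,
    ConvTranspose2d,
    InstanceNorm2d,
    Layer,
    LeakyReLU,
    ReLU,
    Sequential,
    Tanh,
)


def receptive_field(layers: list[tuple[int, int]]) -> int:
    """Analytic receptive field of stacked convolutions.

    ``layers`` is a list of (kernel, stride) pairs in forward order:
    rf = 1 + sum_i (k_i - 1) * prod_{j<i} s_j.
    """
    rf, jump = 1, 1
    for k, s in layers:
        rf += (k - 1) * jump
        jump *= s
    return rf


class UNet(Layer):
    """Encoder-decoder generator with skip connections.

    ``depth`` down/up-sampling levels; input spatial size must be
    divisible by ``2**depth``.
    """

    def __init__(self, in_ch=1, out_ch=1, depth=5, base_channels=32, channel_cap=64,
                 rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.depth = depth
        ch = [min(base_channels * 2**i, channel_cap) for i in range(depth)]
        self.enc_channels = ch

        self.enc: list[Sequential] = []
        prev = in_ch
        for i in range(depth):
            layers: list[Layer] = [Conv2d(prev, ch[i], 4, 2, 1, rng=rng, dtype=dtype)]
            if i > 0:
                layers.append(InstanceNorm2d(ch[i], dtype=dtype))
            layers.append(LeakyReLU(0.2))
            self.enc.append(Sequential(*layers))
            prev = ch[i]

        self.dec: list[Sequential] = []
        d_in = ch[depth - 1]
        for j in range(depth - 1):
            target = ch[depth - 2 - j]
            self.dec.append(
                Sequential(
                    ConvTranspose2d(d_in, target, 4, 2, 1, rng=rng, dtype=dtype),
                    InstanceNorm2d(target, dtype=dtype),
                    ReLU(),
                )
            )
            d_in = 2 * target  # concat with the skip
        self.final = Sequential(
            ConvTranspose2d(d_in, out_ch, 4, 2, 1, rng=rng, dtype=dtype), Tanh()
        )
        self._blocks = self.enc + self.dec + [self.final]

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[-1] % 2**self.depth or x.shape[-2] % 2**self.depth:
            raise ValueError(
                f"input size {x.shape[-2:]} not divisible by 2**depth = {2**self.depth}"
            )
        e = []
        h = x
        for blk in self.enc:
            h = blk.forward(h)
            e.append(h)
        d = e[-1]
        self._concat_split = []
        for j, blk in enumerate(self.dec):
            d = blk.forward(d)
            skip = e[self.depth - 2 - j]
            self._concat_split.append(d.shape[1])
            d = np.concatenate([d, skip], axis=1)
        return self.final.forward(d)

    def backward(self, dy: np.ndarray, accumulate: bool = True) -> np.ndarray:
        g = self.final.backward(dy, accumulate=accumulate)
        skip_grads: list = [None] * self.depth
        for j in reversed(range(len(self.dec))):
            cd = self._concat_split[j]
            skip_grads[self.depth - 2 - j] = g[:, cd:]
            g = self.dec[j].backward(np.ascontiguousarray(g[:, :cd]), accumulate=accumulate)
        for i in reversed(range(self.depth)):
            if skip_grads[i] is not None:
                g = g + skip_grads[i]
            g = self.enc[i].backward(g, accumulate=accumulate)
        return g

    def zero_grad(self) -> None:
        for blk in self._blocks:
            blk.zero_grad()

    def named_params(self) -> dict:
        out = {}
        for i, blk in enumerate(self._blocks):
            out.update(blk.named_params(f"b{i}."))
        return out

    def named_grads(self) -> dict:
        out = {}
        for i, blk in enumerate(self._blocks):
            out.update(blk.named_grads(f"b{i}."))
        return out


class PatchGAN(Layer):
    """Fully convolutional patch discriminator on (input, candidate) pairs.

    ``n_layers`` stride-2 4x4 convolutions with doubling (capped) channel
    counts, one stride-1 convolution, then a 1-channel stride-1 logit map.
    """

    def __init__(self, in_ch=2, base_channels=32, n_layers=3, channel_cap=256,
                 rng=None, dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.kernel_strides: list[tuple[int, int]] = []
        layers: list[Layer] = []
        prev = in_ch
        ch = base_channels
        for i in range(n_layers):
            layers.append(Conv2d(prev, ch, 4, 2, 1, rng=rng, dtype=dtype))
            self.kernel_strides.append((4, 2))
            if i > 0:
                layers.append(InstanceNorm2d(ch, dtype=dtype))
            layers.append(LeakyReLU(0.2))
            prev = ch
            ch = min(ch * 2, channel_cap)
        layers.append(Conv2d(prev, 1, 4, 1, 1, rng=rng, dtype=dtype))
        self.kernel_strides.append((4, 1))
        self.net = Sequential(*layers)

    @property
    def receptive_field(self) -> int:
        """The "fragment diameter": pixels per judged patch."""
        return receptive_field(self.kernel_strides)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.net.forward(x)

    def backward(self, dy: np.ndarray, accumulate: bool = True) -> np.ndarray:
        return self.net.backward(dy, accumulate=accumulate)

    def zero_grad(self) -> None:
        self.net.zero_grad()

    def named_params(self) -> dict:
        return self.net.named_params("d.")

    def named_grads(self) -> dict:
        return self.net.named_grads("d.")
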