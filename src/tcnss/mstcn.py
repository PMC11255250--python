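"""Improved temporal convolutional network trunk.

The trunk is built from dilated causal convolutions: position t of a layer's
output sees only input positions <= t, with taps spaced by the dilation
factor.  Three-layer residual blocks are run at several dilation scales in
parallel (default scales 1, 9, 81, 729, 6561); their outputs are
concatenated over channels and fused by a 1x1 convolution.  Two such
multiscale stacks with independent parameters process the sequence forward
and backward; their outputs are merged by elementwise addition, passed
through a 1x1 convolution, a dense transform with ReLU activation, and
batch normalization.  The forward branch alone is strictly causal; the
merged bidirectional output at position t depends on the whole sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import autodiff as ad
from .nn import BatchNorm, Dropout, Linear, Module, Tensor, init_uniform, no_grad


@dataclass(frozen=True)
class ResBlockSpec:
    """One residual block: stacked causal convolutions plus a skip path."""

    kernel_size: int = 3
    dilation: int = 1
    channels: int = 32
    conv_layers: int = 3
    dropout: float = 0.0

    def __post_init__(self) -> None:
        if self.kernel_size < 1 or self.dilation < 1 or self.conv_layers < 1:
            raise ValueError("kernel_size, dilation, conv_layers must be >= 1")


@dataclass(frozen=True)
class MultiScaleSpec:
    """Parallel residual blocks at several dilation scales, fused by 1x1 conv."""

    scales: tuple[int, ...] = (1, 9, 81, 729, 6561)
    kernel_size: int = 3
    channels: int = 32
    out_width: int = 64
    conv_layers: int = 3
    dropout: float = 0.0

    def __post_init__(self) -> None:
        if not self.scales:
            raise ValueError("at least one scale is required")
        if any(s < 1 for s in self.scales):
            raise ValueError("all scales must be >= 1")
        if any(b >= a for a, b in zip(self.scales[1:], self.scales[:-1])):
            raise ValueError("scales must be strictly increasing")


@dataclass(frozen=True)
class BidirSpec:
    """Forward + backward multiscale stacks with an output transform."""

    multiscale: MultiScaleSpec = field(default_factory=MultiScaleSpec)

    @property
    def out_width(self) -> int:
        return self.multiscale.out_width


def causal_dilated_conv(x: np.ndarray, kernel: np.ndarray,
                        bias: np.ndarray | None = None,
                        dilation: int = 1) -> np.ndarray:
    """Functional dilated causal convolution on a single (L, C_in) matrix.

    ``out[t] = sum_i kernel[i] . x[t - dilation*i]`` with zero left padding.
    """
    with no_grad():
        out = ad.causal_dilated_conv(Tensor(x[None, :, :]), Tensor(kernel),
                                     None if bias is None else Tensor(bias),
                                     dilation=dilation)
    return out.data[0]


class CausalConv1d(Module):
    def __init__(self, d_in: int, d_out: int, kernel_size: int,
                 dilation: int, rng: np.random.Generator):
        super().__init__()
        fan_in = kernel_size * d_in
        self.weight = init_uniform(rng, (kernel_size, d_in, d_out), fan_in)
        self.bias = init_uniform(rng, (d_out,), fan_in)
        self.dilation = dilation

    def __call__(self, x) -> Tensor:
        return ad.causal_dilated_conv(x, self.weight, self.bias,
                                      dilation=self.dilation)


class ResBlock(Module):
    """Causal conv -> ReLU -> dropout, stacked, plus a residual skip path.

    The skip path is the identity when input and output widths match and a
    1x1 projection otherwise; branch and skip are combined by plain
    addition, so zeroing the branch recovers the input exactly.
    """

    def __init__(self, d_in: int, spec: ResBlockSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        self.convs = []
        width = d_in
        for _ in range(spec.conv_layers):
            self.convs.append(CausalConv1d(width, spec.channels,
                                           spec.kernel_size, spec.dilation, rng))
            width = spec.channels
        self.drop = Dropout(spec.dropout, rng)
        self.proj = (Linear(d_in, spec.channels, rng)
                     if d_in != spec.channels else None)

    def __call__(self, x) -> Tensor:
        h = x
        for conv in self.convs:
            h = self.drop(ad.relu(conv(h)))
        skip = x if self.proj is None else self.proj(x)
        return ad.add(h, skip)

    @property
    def receptive_field(self) -> int:
        """Positions back (inclusive of t) visible to the block at position t."""
        s = self.spec
        return 1 + s.conv_layers * (s.kernel_size - 1) * s.dilation


class MSTCN(Module):
    """Multiscale stack: one residual block per scale, concat, 1x1 fusion."""

    def __init__(self, d_in: int, spec: MultiScaleSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        self.blocks = [ResBlock(d_in,
                                ResBlockSpec(kernel_size=spec.kernel_size,
                                             dilation=s,
                                             channels=spec.channels,
                                             conv_layers=spec.conv_layers,
                                             dropout=spec.dropout), rng)
                       for s in spec.scales]
        self.fuse = Linear(len(spec.scales) * spec.channels, spec.out_width, rng)

    def __call__(self, x) -> Tensor:
        outs = [block(x) for block in self.blocks]
        return self.fuse(ad.concat(outs, axis=-1))


class ImprovedTCN(Module):
    """Bidirectional multiscale TCN with fusion and output transform.

    The backward branch runs an independent multiscale stack on the
    position-reversed sequence and re-reverses its output; with padded
    batches the reversal covers only each sequence's valid prefix.  Merged
    output: elementwise addition, 1x1 convolution, dense + ReLU, batch
    normalization.
    """

    def __init__(self, d_in: int, spec: BidirSpec, rng: np.random.Generator):
        super().__init__()
        self.spec = spec
        h = spec.out_width
        self.forward_stack = MSTCN(d_in, spec.multiscale, rng)
        self.backward_stack = MSTCN(d_in, spec.multiscale, rng)
        self.conv1x1 = Linear(h, h, rng)
        self.dense = Linear(h, h, rng)
        self.norm = BatchNorm(h)

    def __call__(self, x: Tensor, lengths: np.ndarray,
                 mask: np.ndarray) -> Tensor:
        if x.shape[1] == 0:
            raise ValueError("empty sequence")
        y_fwd = self.forward_stack(x)
        x_rev = ad.reverse_padded(x, lengths)
        y_bwd = ad.reverse_padded(self.backward_stack(x_rev), lengths)
        merged = ad.add(y_fwd, y_bwd)
        z = self.dense(self.conv1x1(merged))
        return self.norm(ad.relu(z), mask)


def run_trunk(module: Module, x: np.ndarray) -> np.ndarray:
    """Evaluation-mode convenience: run a trunk module on one (L, D) matrix."""
    was_training = module.training
    module.eval()
    L = x.shape[0]
    with no_grad():
        if isinstance(module, ImprovedTCN):
            out = module(Tensor(x[None]), np.array([L]), np.ones((1, L, 1)))
        else:
            out = module(Tensor(x[None]))
    if was_training:
        module.train()
    return out.data[0]
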