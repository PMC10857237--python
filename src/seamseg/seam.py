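"""SEAM channel attention: CSMM branches, pooled FC gating, exponential re-weighting.

The module re-weights decoder features ``x`` (N, C, H, W) in four steps:

1. *CSMM branches.*  Each of ``n_branches`` channel-and-spatial mixing
   modules applies a depthwise separable convolution (a ``patch_size`` ×
   ``patch_size`` depthwise stage followed by a 1×1 pointwise stage), a
   smooth activation, and a residual connection from its input.
2. *Global pooling.*  Every branch output is average-pooled over (H, W) to
   a per-channel descriptor; the branch descriptors are averaged.
3. *FC gating.*  Two fully connected layers (C → hidden → C, hidden =
   ``max(C // fc_reduction, hidden_floor)``) followed by a sigmoid produce
   a gate g ∈ (0, 1) per (batch, channel).
4. *Exponential re-weighting.*  The output is ``x ⊙ exp(g)`` with the
   multiplier broadcast over (H, W), so every channel is scaled by a factor
   in [1, e].  The exponential maps the sigmoid's (0, 1) range to (1, e),
   which boosts attended channels without ever suppressing a feature below
   its input magnitude.

Step 4 exponentiates the gate itself; the alternative of exponentiating the
gate multiplied by the (unbounded) pooled descriptor is available via
``gate_times_pooled=True`` but carries no [1, e] range guarantee.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from . import nn

E = float(np.e)


@dataclass
class SeamConfig:
    """Hyperparameters of the SEAM attention block.

    channels: width C of the feature map the block attaches to.
    patch_size: kernel extent of the depthwise stage (odd; default 7).
    n_branches: number of parallel CSMM branches (default 3).
    fc_reduction: bottleneck ratio of the gating MLP (default 4).
    hidden_floor: lower bound on the bottleneck width (default 8).
    residual: add the branch input back after the separable conv + activation.
    gate_times_pooled: exponentiate gate × pooled descriptor instead of the gate.
    """

    channels: int
    patch_size: int = 7
    n_branches: int = 3
    fc_reduction: int = 4
    hidden_floor: int = 8
    residual: bool = True
    gate_times_pooled: bool = False
    activation: str = "gelu"
    fc_bias: bool = True
    check_bounds: bool = False

    def __post_init__(self):
        if self.patch_size % 2 == 0:
            raise ValueError(f"patch_size must be odd, got {self.patch_size}")
        if self.n_branches < 1 or self.fc_reduction < 1:
            raise ValueError("n_branches and fc_reduction must be >= 1")

    @property
    def hidden_width(self) -> int:
        return max(self.channels // self.fc_reduction, self.hidden_floor, 1)


@dataclass
class AttentionWeights:
    """Per-(batch, channel) gate ``g`` in (0, 1) and multiplier ``scale`` in [1, e]."""

    g: np.ndarray
    scale: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.scale is None:
            self.scale = np.exp(self.g)


def _activation(name: str) -> nn.Module:
    try:
        return {"gelu": nn.GELU, "relu": nn.ReLU, "sigmoid": nn.Sigmoid}[name]()
    except KeyError:
        raise ValueError(f"unknown activation {name!r}") from None


class CSMM(nn.Module):
    """Channel and spatial mixing module.

    Depthwise conv (spatial mixing, kernel = patch_size, same padding)
    → pointwise 1×1 conv (channel mixing) → activation → + residual.
    """

    def __init__(self, cfg: SeamConfig, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.cfg = cfg
        k = cfg.patch_size
        self.depthwise = nn.DepthwiseConv2d(cfg.channels, k, padding=k // 2,
                                            rng=rng, dtype=dtype)
        self.pointwise = nn.Conv2d(cfg.channels, cfg.channels, 1, padding=0,
                                   rng=rng, dtype=dtype)
        self.act = _activation(cfg.activation)

    def forward(self, x: Tensor) -> Tensor:
        out = self.act(self.pointwise(self.depthwise(x)))
        if self.cfg.residual:
            out = out + x
        return out


class SEAM(nn.Module):
    """The full attention block; preserves the input shape."""

    def __init__(self, cfg: SeamConfig, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.cfg = cfg
        for i in range(cfg.n_branches):
            setattr(self, f"branch{i}", CSMM(cfg, rng, dtype))
        self._branches = [getattr(self, f"branch{i}") for i in range(cfg.n_branches)]
        h = cfg.hidden_width
        self.fc1 = nn.Linear(cfg.channels, h, bias=cfg.fc_bias, rng=rng, dtype=dtype)
        self.fc2 = nn.Linear(h, cfg.channels, bias=cfg.fc_bias, rng=rng, dtype=dtype)
        self.fc_act = _activation(cfg.activation)

    # exposed stages --------------------------------------------------------
    def branch_outputs(self, x: Tensor) -> list[Tensor]:
        if x.data.shape[1] != self.cfg.channels:
            raise ValueError(f"expected {self.cfg.channels} channels, "
                             f"got {x.data.shape[1]}")
        return [b(x) for b in self._branches]

    def gate(self, branch_outputs: list[Tensor]) -> Tensor:
        """Pool each branch over (H, W), average branches, gate through the MLP."""
        shapes = {b.data.shape for b in branch_outputs}
        if len(shapes) != 1:
            raise ValueError(f"branch outputs disagree in shape: {shapes}")
        pooled = [b.mean(axis=(2, 3)) for b in branch_outputs]  # (N, C) each
        y = pooled[0]
        for p in pooled[1:]:
            y = y + p
        y = y * ag.as_tensor(np.asarray(1.0 / len(pooled), dtype=y.dtype))
        g = ag.sigmoid(self.fc2(self.fc_act(self.fc1(y))))
        if self.cfg.gate_times_pooled:
            g = g * y
        return g

    def forward(self, x: Tensor) -> Tensor:
        g = self.gate(self.branch_outputs(x))
        return exp_reweight(x, g, validate=self.cfg.check_bounds
                            or not self.cfg.gate_times_pooled)

    def attention_weights(self, x: Tensor) -> AttentionWeights:
        """Inference helper: the gate and multiplier actually applied to ``x``."""
        g = self.gate(self.branch_outputs(x)).data
        return AttentionWeights(g=np.asarray(g))


def exp_reweight(x: Tensor, g: Tensor, validate: bool = True) -> Tensor:
    """Scale ``x`` per (batch, channel) by exp(g), broadcast over (H, W).

    With g in [0, 1] every multiplier lies in [1, e]; ``validate`` enforces
    the gate range.
    """
    g = ag.as_tensor(g, getattr(x, "dtype", None))
    if validate:
        gd = g.data
        if np.any(gd < 0) or np.any(gd > 1):
            raise ValueError("gate values outside [0, 1]; "
                             "the exponential re-weighting contract requires "
                             "g in [0, 1]")
    scale = ag.exp(ag.reshape(g, (*g.data.shape, 1, 1)))
    return x * scale
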