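"""U-Net, UNet++ and SEAM-UNet++ segmentation backbones.

UNet++ arranges convolutional nodes on a triangular grid ``X[i][j]``
(encoder depth i, skip stage j, i + j <= depth - 1).  Column j = 0 is the
plain encoder; every later node consumes all earlier nodes of its row plus
an upsampled neighbour from the row below:

    X[i][j] = conv_block(concat(X[i][0], ..., X[i][j-1], up(X[i+1][j-1])))

The last top-row node ``X[0][depth-1]`` feeds a 1×1 convolution + sigmoid
head.  SEAM-UNet++ inserts a single SEAM attention block between that node
and the head; nothing else differs, so toggling the block isolates its
contribution exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from . import nn
from .seam import SEAM, SeamConfig

MODEL_NAMES = ("unet", "unetpp", "seam_unetpp")


@dataclass
class ModelConfig:
    """Architecture hyperparameters shared by all three models."""

    in_channels: int = 3
    depth: int = 5
    base_width: int = 32
    widths: tuple[int, ...] | None = None
    seam: SeamConfig | None = None
    deep_supervision: bool = False
    out_channels: int = 1

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.widths is None:
            self.widths = tuple(self.base_width * 2 ** d for d in range(self.depth))
        else:
            self.widths = tuple(self.widths)
        if len(self.widths) != self.depth:
            raise ValueError("widths length must equal depth")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.seam is not None:
            d["seam"] = dataclasses.asdict(self.seam)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        if d.get("seam"):
            d["seam"] = SeamConfig(**d["seam"])
        return cls(**d)


class ConvBlock(nn.Module):
    """Two 3x3 conv -> batch-norm -> ReLU stages; spatial size preserved."""

    def __init__(self, in_ch: int, out_ch: int, rng, dtype=np.float32):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, out_ch, 3, padding=1, rng=rng, dtype=dtype)
        self.bn1 = nn.BatchNorm2d(out_ch, dtype=dtype)
        self.conv2 = nn.Conv2d(out_ch, out_ch, 3, padding=1, rng=rng, dtype=dtype)
        self.bn2 = nn.BatchNorm2d(out_ch, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        x = ag.relu(self.bn1(self.conv1(x)))
        return ag.relu(self.bn2(self.conv2(x)))


class _UpConv(nn.Module):
    """Bilinear 2x upsampling followed by a 1x1 channel-reducing convolution."""

    def __init__(self, in_ch: int, out_ch: int, rng, dtype=np.float32):
        super().__init__()
        self.conv = nn.Conv2d(in_ch, out_ch, 1, padding=0, rng=rng, dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(ag.upsample_bilinear2x(x))


def _check_divisible(shape, depth):
    h, w = shape[-2:]
    f = 2 ** (depth - 1)
    if h % f or w % f:
        raise ValueError(
            f"input spatial size {h}x{w} must be divisible by {f} "
            f"(2**(depth-1)); pad the input or use predict()'s auto-padding")


class _SegmentationModel(nn.Module):
    """Shared scaffolding: encoder column, head, sigmoid output."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config

    def forward(self, x, return_nodes: bool = False):
        raise NotImplementedError

    def predict_proba(self, images: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Run inference (eval mode) on a (N, 3, H, W) float array."""
        self.eval()
        outs = []
        for i in range(0, len(images), batch_size):
            batch = ag.Tensor(np.asarray(images[i:i + batch_size], dtype=np.float32))
            outs.append(self.forward(batch).data)
        self.train()
        return np.concatenate(outs, axis=0)


class UNet(_SegmentationModel):
    """Plain U-Net: encoder column + single decoder path with simple skips."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        super().__init__(config)
        rng = rng or np.random.default_rng()
        w = config.widths
        d = config.depth
        self.pool = nn.MaxPool2x2()
        for i in range(d):
            in_ch = config.in_channels if i == 0 else w[i - 1]
            setattr(self, f"enc{i}", ConvBlock(in_ch, w[i], rng, dtype))
        for i in range(d - 1):
            setattr(self, f"up{i}", _UpConv(w[i + 1], w[i], rng, dtype))
            setattr(self, f"dec{i}", ConvBlock(2 * w[i], w[i], rng, dtype))
        self.head = nn.Conv2d(w[0], config.out_channels, 1, padding=0,
                              rng=rng, dtype=dtype)

    def forward(self, x: Tensor, return_nodes: bool = False):
        _check_divisible(x.data.shape, self.config.depth)
        d = self.config.depth
        enc = []
        h = x
        for i in range(d):
            h = getattr(self, f"enc{i}")(h if i == 0 else self.pool(enc[i - 1]))
            enc.append(h)
        h = enc[-1]
        for i in range(d - 2, -1, -1):
            up = getattr(self, f"up{i}")(h)
            h = getattr(self, f"dec{i}")(ag.concat([enc[i], up], axis=1))
        out = ag.sigmoid(self.head(h))
        if return_nodes:
            return out, {"encoder": enc}
        return out


class UNetPP(_SegmentationModel):
    """Nested U-Net with dense skip connections; optional SEAM before the head."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator | None = None,
                 dtype=np.float32):
        super().__init__(config)
        rng = rng or np.random.default_rng()
        w = config.widths
        d = config.depth
        self.pool = nn.MaxPool2x2()
        n_nodes = 0
        for i in range(d):
            for j in range(d - i):
                n_nodes += 1
                if j == 0:
                    in_ch = config.in_channels if i == 0 else w[i - 1]
                else:
                    setattr(self, f"up_{i}_{j}", _UpConv(w[i + 1], w[i], rng, dtype))
                    in_ch = (j + 1) * w[i]
                setattr(self, f"node_{i}_{j}", ConvBlock(in_ch, w[i], rng, dtype))
        assert n_nodes == d * (d + 1) // 2, "node grid must be triangular"
        if config.seam is not None:
            if config.seam.channels != w[0]:
                raise ValueError(
                    f"SEAM channels ({config.seam.channels}) must match the "
                    f"top-row width ({w[0]})")
            self.seam = SEAM(config.seam, rng=rng, dtype=dtype)
        else:
            self.seam = None
        if config.deep_supervision:
            for j in range(1, d):
                setattr(self, f"head{j}", nn.Conv2d(w[0], config.out_channels, 1,
                                                    padding=0, rng=rng, dtype=dtype))
            self.head = getattr(self, f"head{d - 1}")
        else:
            self.head = nn.Conv2d(w[0], config.out_channels, 1, padding=0,
                                  rng=rng, dtype=dtype)

    def forward(self, x: Tensor, return_nodes: bool = False):
        _check_divisible(x.data.shape, self.config.depth)
        d = self.config.depth
        grid: dict[tuple[int, int], Tensor] = {}
        for j in range(d):
            for i in range(d - j):
                if j == 0:
                    inp = x if i == 0 else self.pool(grid[(i - 1, 0)])
                    grid[(i, j)] = getattr(self, f"node_{i}_{j}")(inp)
                else:
                    skips = [grid[(i, k)] for k in range(j)]
                    up = getattr(self, f"up_{i}_{j}")(grid[(i + 1, j - 1)])
                    grid[(i, j)] = getattr(self, f"node_{i}_{j}")(
                        ag.concat(skips + [up], axis=1))
        top = grid[(0, d - 1)]
        if self.seam is not None:
            top = self.seam(top)
        if self.config.deep_supervision:
            probs = [ag.sigmoid(getattr(self, f"head{j}")(
                grid[(0, j)] if j < d - 1 else top)) for j in range(1, d)]
            out = probs[0]
            for p in probs[1:]:
                out = out + p
            out = out * ag.as_tensor(np.asarray(1.0 / len(probs), dtype=x.dtype))
        else:
            out = ag.sigmoid(self.head(top))
        if return_nodes:
            return out, {"grid": grid, "encoder": [grid[(i, 0)] for i in range(d)]}
        return out


def build_model(name: str, config: ModelConfig,
                rng: np.random.Generator | None = None,
                dtype=np.float32) -> _SegmentationModel:
    """Build one of the three compared models from a shared configuration.

    ``unet`` and ``unetpp`` ignore ``config.seam``; ``seam_unetpp`` requires
    it (a default 7-patch, 3-branch block is created if absent).
    """
    if name == "unet":
        cfg = dataclasses.replace(config, seam=None)
        return UNet(cfg, rng=rng, dtype=dtype)
    if name == "unetpp":
        cfg = dataclasses.replace(config, seam=None)
        return UNetPP(cfg, rng=rng, dtype=dtype)
    if name == "seam_unetpp":
        seam = config.seam or SeamConfig(channels=config.widths[0])
        cfg = dataclasses.replace(config, seam=seam)
        return UNetPP(cfg, rng=rng, dtype=dtype)
    raise ValueError(f"unknown model name {name!r}; expected one of {MODEL_NAMES}")
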