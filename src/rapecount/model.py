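"""RapeNet and RapeNet+ density-regression architectures.

The backbone is six pyramidal-convolution (PyConv) blocks. A PyConv block
runs several convolutions with *different kernel sizes* in parallel on the
same input and concatenates their outputs along channels, so each block sees
the scene at several receptive-field scales at once — flower clusters in
nadir imagery range from a few pixels to large adhering clumps. The number
of pyramid levels rises over blocks 1-3 and falls over blocks 4-6. Blocks
1-3 downsample by 2 each, giving an output stride of 8; a 1x1 regression
head with a non-negativity clamp emits the density map, whose sum is the
predicted count.

RapeNet+ inserts a coordinate-attention branch after blocks 2 and 4: input
features are average-pooled along height and width separately, jointly
encoded by a 1x1 bottleneck, then expanded into per-row and per-column
sigmoid gates that reweight the feature map position-wise.

Grouped convolutions at the larger kernels keep the capacity at the few-MB
scale; ``width_multiplier`` scales every channel count so the same topology
trains on a CPU in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .density_loss import DensityMap
from .nn import Abs, BatchNorm2d, Conv2d, Layer, Param, ReLU, Sigmoid

__all__ = [
    "PyConvSpec", "NetworkConfig", "PyConvBlock", "CoordinateAttention",
    "RapeNet", "build_model", "parameter_capacity",
    "default_rapenet_config", "default_rapenet_plus_config",
    "save_weights", "load_weights",
]

_KERNEL_POOL = (3, 5, 7, 9)
_GROUP_FOR_KERNEL = {3: 1, 5: 4, 7: 8, 9: 16}


@dataclass(frozen=True)
class PyConvSpec:
    """One pyramidal block: parallel (kernel, out_channels, groups) levels."""

    levels: tuple[tuple[int, int, int], ...]
    stride: int = 1

    def __post_init__(self) -> None:
        kernels = [k for k, _, _ in self.levels]
        if not kernels:
            raise ValueError("a PyConv block needs at least one level")
        if len(set(kernels)) != len(kernels) or any(k % 2 == 0 for k in kernels):
            raise ValueError("kernel sizes must be odd and distinct")

    @property
    def out_channels(self) -> int:
        return sum(c for _, c, _ in self.levels)


def _fit_groups(wanted: int, in_ch: int, out_ch: int) -> int:
    g = min(wanted, in_ch, out_ch)
    while in_ch % g or out_ch % g:
        g -= 1
    return g


def _make_spec(in_ch: int, out_ch: int, n_levels: int, stride: int) -> PyConvSpec:
    kernels = _KERNEL_POOL[:n_levels]
    base, rem = divmod(out_ch, n_levels)
    chans = [base + (1 if i < rem else 0) for i in range(n_levels)]
    levels = tuple(
        (k, c, _fit_groups(_GROUP_FOR_KERNEL[k], in_ch, c))
        for k, c in zip(kernels, chans)
    )
    return PyConvSpec(levels, stride)


@dataclass
class NetworkConfig:
    """Topology of a RapeNet-family model.

    ``attention_after`` is empty for RapeNet and {2, 4} for RapeNet+ (1-based
    block indices). ``width_multiplier`` scales all channel widths; the
    published-scale default is 1.0 and CPU tests use 0.25.
    """

    block_channels: tuple[int, ...] = (64, 128, 256, 256, 128, 64)
    pyramid_levels: tuple[int, ...] = (2, 3, 4, 4, 3, 2)
    block_strides: tuple[int, ...] = (2, 2, 2, 1, 1, 1)
    attention_after: frozenset[int] = frozenset()
    attention_reduction: int = 8
    width_multiplier: float = 1.0
    in_channels: int = 3
    pad_mode: str = "zeros"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (len(self.block_channels) == len(self.pyramid_levels)
                == len(self.block_strides) == 6):
            raise ValueError("RapeNet-family backbones have exactly six blocks")
        lv = self.pyramid_levels
        if not all(lv[i] <= lv[i + 1] for i in range(2)):
            raise ValueError("pyramid level counts must rise over blocks 1-3")
        if not all(lv[i] >= lv[i + 1] for i in range(3, 5)):
            raise ValueError("pyramid level counts must fall over blocks 4-6")
        self.attention_after = frozenset(self.attention_after)

    @property
    def output_stride(self) -> int:
        return int(np.prod(self.block_strides))

    def scaled_channels(self) -> tuple[int, ...]:
        return tuple(max(4, int(round(c * self.width_multiplier)))
                     for c in self.block_channels)

    def block_specs(self) -> tuple[PyConvSpec, ...]:
        chans = self.scaled_channels()
        specs = []
        prev = self.in_channels
        for c, n, s in zip(chans, self.pyramid_levels, self.block_strides):
            specs.append(_make_spec(prev, c, n, s))
            prev = c
        return tuple(specs)

    def to_yaml(self, path: str | Path | None = None) -> str:
        data = {
            "block_channels": list(self.block_channels),
            "pyramid_levels": list(self.pyramid_levels),
            "block_strides": list(self.block_strides),
            "attention_after": sorted(self.attention_after),
            "attention_reduction": self.attention_reduction,
            "width_multiplier": self.width_multiplier,
            "in_channels": self.in_channels,
            "pad_mode": self.pad_mode,
            "seed": self.seed,
        }
        text = yaml.safe_dump(data)
        if path is not None:
            Path(path).write_text(text)
        return text

    @staticmethod
    def from_yaml(source: str | Path) -> "NetworkConfig":
        if isinstance(source, Path) or ("\n" not in str(source) and Path(source).exists()):
            text = Path(source).read_text()
        else:
            text = str(source)
        data = yaml.safe_load(text)
        data["block_channels"] = tuple(data["block_channels"])
        data["pyramid_levels"] = tuple(data["pyramid_levels"])
        data["block_strides"] = tuple(data["block_strides"])
        data["attention_after"] = frozenset(data["attention_after"])
        return NetworkConfig(**data)


def default_rapenet_config(width_multiplier: float = 1.0, **kw) -> NetworkConfig:
    return NetworkConfig(width_multiplier=width_multiplier, **kw)


def default_rapenet_plus_config(width_multiplier: float = 1.0, **kw) -> NetworkConfig:
    return NetworkConfig(width_multiplier=width_multiplier,
                         attention_after=frozenset({2, 4}), **kw)


class PyConvBlock(Layer):
    """Parallel multi-kernel convolutions, channel-concatenated, BN + ReLU."""

    def __init__(self, in_ch: int, spec: PyConvSpec, *, pad_mode: str = "zeros",
                 rng: np.random.Generator | None = None) -> None:
        self.spec = spec
        self.convs = [
            Conv2d(in_ch, c, k, stride=spec.stride, groups=g, bias=False,
                   pad_mode=pad_mode, rng=rng)
            for k, c, g in spec.levels
        ]
        self.bn = BatchNorm2d(spec.out_channels)
        self.act = ReLU()
        self._split = np.cumsum([c for _, c, _ in spec.levels])[:-1]

    def params(self) -> list[Param]:
        out = [p for conv in self.convs for p in conv.params()]
        return out + self.bn.params()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        outs = [conv.forward(x, train) for conv in self.convs]
        y = np.concatenate(outs, axis=0)
        return self.act.forward(self.bn.forward(y, train), train)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        g = self.bn.backward(self.act.backward(gout))
        gx = None
        for conv, gpart in zip(self.convs, np.split(g, self._split, axis=0)):
            gi = conv.backward(gpart)
            gx = gi if gx is None else gx + gi
        return gx


class CoordinateAttention(Layer):
    """Position-aware channel reweighting from 1-D height/width pooling.

    out(c, i, j) = in(c, i, j) * g_h(c, i) * g_w(c, j), with the gates
    produced by a shared 1x1 bottleneck over the pooled descriptors followed
    by per-direction 1x1 expansions and a sigmoid. With every transform
    parameter zeroed both gates are exactly 0.5, so the module scales its
    input by 1/4 — a useful analytic probe.
    """

    def __init__(self, ch: int, reduction: int = 8, *,
                 rng: np.random.Generator | None = None) -> None:
        if reduction > ch:
            raise ValueError(f"reduction {reduction} exceeds channel count {ch}")
        if ch % reduction:
            raise ValueError("channel count must be divisible by reduction")
        mid = ch // reduction
        self.ch, self.mid = ch, mid
        self.conv1 = Conv2d(ch, mid, 1, rng=rng)
        self.bn = BatchNorm2d(mid)
        self.act = ReLU()
        self.conv_h = Conv2d(mid, ch, 1, rng=rng)
        self.conv_w = Conv2d(mid, ch, 1, rng=rng)
        self.sig_h = Sigmoid()
        self.sig_w = Sigmoid()
        self._cache: tuple | None = None

    def params(self) -> list[Param]:
        return (self.conv1.params() + self.bn.params()
                + self.conv_h.params() + self.conv_w.params())

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        c, h, w = x.shape
        pool_h = x.mean(axis=2)  # (C, H)
        pool_w = x.mean(axis=1)  # (C, W)
        y = np.concatenate([pool_h, pool_w], axis=1)[:, :, None]  # (C, H+W, 1)
        y = self.act.forward(self.bn.forward(self.conv1.forward(y, train), train), train)
        yh, yw = y[:, :h], y[:, h:]
        gh = self.sig_h.forward(self.conv_h.forward(yh, train), train)[:, :, 0]
        gw = self.sig_w.forward(self.conv_w.forward(yw, train), train)[:, :, 0]
        out = x * gh[:, :, None] * gw[:, None, :]
        if train:
            self._cache = (x, gh, gw)
        return out.astype(np.float32)

    def backward(self, gout: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward called before forward(train=True)")
        x, gh, gw = self._cache
        c, h, w = x.shape
        gx_direct = gout * gh[:, :, None] * gw[:, None, :]
        g_gh = (gout * x * gw[:, None, :]).sum(axis=2)  # (C, H)
        g_gw = (gout * x * gh[:, :, None]).sum(axis=1)  # (C, W)
        gyh = self.conv_h.backward(self.sig_h.backward(g_gh[:, :, None]))
        gyw = self.conv_w.backward(self.sig_w.backward(g_gw[:, :, None]))
        gy = np.concatenate([gyh, gyw], axis=1)
        gpool = self.conv1.backward(self.bn.backward(self.act.backward(gy)))[:, :, 0]
        gpool_h, gpool_w = gpool[:, :h], gpool[:, h:]
        gx = gx_direct + gpool_h[:, :, None] / w + gpool_w[:, None, :] / h
        self._cache = None
        return gx.astype(np.float32)


class RapeNet:
    """Six-block PyConv density-regression network (RapeNet / RapeNet+).

    The variant is decided by ``cfg.attention_after``: empty gives RapeNet,
    {2, 4} the attention-augmented RapeNet+.
    """

    def __init__(self, cfg: NetworkConfig) -> None:
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        chans = cfg.scaled_channels()
        self.blocks: list[Layer] = []
        self.attention: dict[int, CoordinateAttention] = {}
        prev = cfg.in_channels
        for idx, spec in enumerate(cfg.block_specs(), start=1):
            self.blocks.append(PyConvBlock(prev, spec, pad_mode=cfg.pad_mode, rng=rng))
            prev = spec.out_channels
            if idx in cfg.attention_after:
                red = _fit_groups(cfg.attention_reduction, prev, prev)
                self.attention[idx] = CoordinateAttention(prev, red, rng=rng)
        self.head = Conv2d(chans[-1], 1, 1, rng=rng)
        self.head_act = Abs()

    # --- plumbing -------------------------------------------------------
    def params(self) -> list[Param]:
        out: list[Param] = []
        for b in self.blocks:
            out += b.params()
        for a in self.attention.values():
            out += a.params()
        out += self.head.params()
        return out

    def parameter_count(self) -> int:
        return sum(p.size for p in self.params())

    # --- forward / backward --------------------------------------------
    def forward(self, image: np.ndarray, train: bool = False) -> DensityMap:
        """image: (3, H, W) float in [0, 1]; H, W divisible by output stride."""
        image = np.asarray(image, dtype=np.float32)
        if image.ndim != 3 or image.shape[0] != self.cfg.in_channels:
            raise ValueError(f"expected ({self.cfg.in_channels}, H, W) input")
        stride = self.cfg.output_stride
        if image.shape[1] % stride or image.shape[2] % stride:
            raise ValueError(
                f"input {image.shape[1]}x{image.shape[2]} not divisible by "
                f"output stride {stride}"
            )
        x = image
        for idx, block in enumerate(self.blocks, start=1):
            x = block.forward(x, train)
            if idx in self.attention:
                x = self.attention[idx].forward(x, train)
        x = self.head_act.forward(self.head.forward(x, train), train)
        return DensityMap(x[0].astype(float), stride=stride)

    def backward(self, grad_density: np.ndarray) -> None:
        """Backpropagate a density-map gradient; accumulates Param.grad."""
        g = np.asarray(grad_density, dtype=np.float32)[None, :, :]
        g = self.head.backward(self.head_act.backward(g))
        for idx in range(len(self.blocks), 0, -1):
            if idx in self.attention:
                g = self.attention[idx].backward(g)
            g = self.blocks[idx - 1].backward(g)

    def predict(self, image: np.ndarray) -> DensityMap:
        return self.forward(image, train=False)

    # --- state snapshots (parameters AND normalization running stats) ---
    def _bn_layers(self):
        bns = [b.bn for b in self.blocks]
        bns += [a.bn for a in self.attention.values()]
        return bns

    def _state_refs(self) -> list[np.ndarray]:
        arrs = [p.value for p in self.params()]
        for bn in self._bn_layers():
            arrs += [bn.running_mean, bn.running_var]
        return arrs

    def get_state(self) -> list[np.ndarray]:
        """Copy of all weights and running statistics (for checkpointing)."""
        return [a.copy() for a in self._state_refs()]

    def set_state(self, state: list[np.ndarray]) -> None:
        refs = self._state_refs()
        if len(refs) != len(state):
            raise ValueError("state does not match this model")
        for ref, val in zip(refs, state):
            ref[...] = val


def build_model(cfg: NetworkConfig) -> RapeNet:
    return RapeNet(cfg)


def parameter_capacity(model_or_cfg: RapeNet | NetworkConfig) -> int:
    """Total trainable parameters x 4 bytes (float32), in bytes."""
    model = (model_or_cfg if isinstance(model_or_cfg, RapeNet)
             else RapeNet(model_or_cfg))
    return 4 * model.parameter_count()


def _state_arrays(model: RapeNet) -> dict[str, np.ndarray]:
    state: dict[str, np.ndarray] = {}
    for i, p in enumerate(model.params()):
        state[f"param_{i:04d}"] = p.value
    bns = [l for b in model.blocks for l in (b.bn,)]
    bns += [a.bn for a in model.attention.values()]
    for i, bn in enumerate(bns):
        state[f"running_mean_{i:02d}"] = bn.running_mean
        state[f"running_var_{i:02d}"] = bn.running_var
    return state


def save_weights(model: RapeNet, path: str | Path) -> None:
    """Save weights (config + arrays) to an .npz container."""
    state = _state_arrays(model)
    state["__config__"] = np.frombuffer(
        model.cfg.to_yaml().encode(), dtype=np.uint8
    ).copy()
    np.savez(path, **state)


def load_weights(path: str | Path) -> RapeNet:
    with np.load(path) as data:
        cfg = NetworkConfig.from_yaml(bytes(data["__config__"]).decode())
        model = RapeNet(cfg)
        for i, p in enumerate(model.params()):
            p.value[...] = data[f"param_{i:04d}"]
        bns = [b.bn for b in model.blocks] + [a.bn for a in model.attention.values()]
        for i, bn in enumerate(bns):
            bn.running_mean[...] = data[f"running_mean_{i:02d}"]
            bn.running_var[...] = data[f"running_var_{i:02d}"]
    return model
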