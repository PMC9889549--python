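"""Volume feature extraction: a pluggable 3D CNN backbone maps a normalized
volume (D, H, W) to a channelled feature map (C, D', H', W') on which the
attention encoders operate.

Backbones are registered by name so experiments can swap a desk-scale CNN
for a deeper residual network without touching the encoders.  The default
``small_cnn`` is a 3-block strided 3D CNN; ``resnet3d`` adds residual
blocks in the ResNet style.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .nn import Conv3d, Module, seeded_rng

__all__ = ["FeatureMap", "Backbone", "SmallCNN3D", "ResNet3D",
           "register_backbone", "build_backbone", "extract_feature_maps",
           "BACKBONES"]


@dataclass
class FeatureMap:
    """Backbone output: values (C, D', H', W'), all finite."""

    values: np.ndarray

    def __post_init__(self):
        if self.values.ndim != 4:
            raise ValueError(f"feature map must be 4-D (C,D',H',W'), got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature map contains non-finite values")

    @property
    def shape(self):
        return self.values.shape


class Backbone(Module):
    """Interface: __call__(x: Tensor (N,1,D,H,W)) -> Tensor (N,C,D',H',W')
    and output_shape((D,H,W)) -> (C,D',H',W') declared ahead of the pass.

    Backbones are built from a sequence of stages.  :meth:`calibrate`
    freezes per-channel normalization statistics after every stage from a
    set of training volumes (a frozen batch-norm): without it, a random
    conv stack on low-contrast volumes collapses to a near-constant output
    and the attention encoders downstream see no usable variation.
    """

    out_channels: int

    def output_shape(self, input_shape) -> tuple:
        raise NotImplementedError

    def _stages(self) -> list:
        """Callables applied in order; normalization is inserted after each."""
        raise NotImplementedError

    def calibrate(self, volumes: np.ndarray):
        """Freeze per-stage, per-channel feature statistics on ``volumes``
        (an (N, 1, D, H, W) array)."""
        self._norms = []
        x = np.asarray(volumes, dtype=float)
        for stage in self._stages():
            x = stage(Tensor(x)).data
            mu = x.mean(axis=(0, 2, 3, 4))
            sd = x.std(axis=(0, 2, 3, 4))
            sd = np.where(sd < 1e-8, 1.0, sd)
            self._norms.append((mu.reshape(1, -1, 1, 1, 1), sd.reshape(1, -1, 1, 1, 1)))
            x = (x - self._norms[-1][0]) / self._norms[-1][1]

    def __call__(self, x: Tensor) -> Tensor:
        norms = getattr(self, "_norms", None)
        for i, stage in enumerate(self._stages()):
            x = stage(x)
            if norms is not None:
                mu, sd = norms[i]
                x = (x - Tensor(mu)) * Tensor(1.0 / sd)
        return x


def _conv_out(size: int, kernel: int, stride: int, pad: int) -> int:
    return (size + 2 * pad - kernel) // stride + 1


class SmallCNN3D(Backbone):
    """Three strided conv+ReLU blocks; desk-scale default.

    On an (8, 16, 16) volume with channels (4, 8, C) the output grid is
    (C, 4, 4, 4): depth halves once, the in-plane grid halves twice.
    """

    def __init__(self, out_channels: int = 12, seed: int = 0):
        rng = seeded_rng(seed)
        c1, c2 = 4, 8
        self.conv1 = Conv3d(1, c1, 3, stride=(2, 2, 2), padding=(1, 1, 1), rng=rng)
        self.conv2 = Conv3d(c1, c2, 3, stride=(1, 2, 2), padding=(1, 1, 1), rng=rng)
        self.conv3 = Conv3d(c2, out_channels, 3, stride=(1, 1, 1), padding=(1, 1, 1), rng=rng)
        self.out_channels = out_channels
        self._specs = [(3, (2, 2, 2), 1), (3, (1, 2, 2), 1), (3, (1, 1, 1), 1)]

    def output_shape(self, input_shape):
        d, h, w = input_shape
        for k, (sd, sh, sw), p in self._specs:
            d, h, w = _conv_out(d, k, sd, p), _conv_out(h, k, sh, p), _conv_out(w, k, sw, p)
        return (self.out_channels, d, h, w)

    def _stages(self):
        return [lambda x: self.conv1(x).relu(),
                lambda x: self.conv2(x).relu(),
                lambda x: self.conv3(x).relu()]


class _ResidualBlock3D(Module):
    def __init__(self, c: int, rng):
        self.conv_a = Conv3d(c, c, 3, padding=(1, 1, 1), rng=rng)
        self.conv_b = Conv3d(c, c, 3, padding=(1, 1, 1), rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        return (self.conv_b(self.conv_a(x).relu()) + x).relu()


class ResNet3D(Backbone):
    """Residual-style 3D CNN: a strided stem followed by residual blocks.

    A compact network in the spirit of deep residual image backbones; depth
    and width are configurable rather than fixed at 50 layers.
    """

    def __init__(self, out_channels: int = 12, n_blocks: int = 2, seed: int = 0):
        rng = seeded_rng(seed)
        self.stem1 = Conv3d(1, out_channels // 2, 3, stride=(2, 2, 2), padding=(1, 1, 1), rng=rng)
        self.stem2 = Conv3d(out_channels // 2, out_channels, 3, stride=(1, 2, 2),
                            padding=(1, 1, 1), rng=rng)
        self.blocks = [_ResidualBlock3D(out_channels, rng) for _ in range(n_blocks)]
        self.out_channels = out_channels

    def output_shape(self, input_shape):
        d, h, w = input_shape
        d, h, w = _conv_out(d, 3, 2, 1), _conv_out(h, 3, 2, 1), _conv_out(w, 3, 2, 1)
        h, w = _conv_out(h, 3, 2, 1), _conv_out(w, 3, 2, 1)
        return (self.out_channels, d, h, w)

    def _stages(self):
        return ([lambda x: self.stem1(x).relu(), lambda x: self.stem2(x).relu()]
                + list(self.blocks))


BACKBONES: dict[str, type] = {}


def register_backbone(name: str, cls: type):
    BACKBONES[name] = cls


register_backbone("small_cnn", SmallCNN3D)
register_backbone("resnet3d", ResNet3D)


def build_backbone(spec: str | dict | Backbone, out_channels: int = 12,
                   seed: int = 0) -> Backbone:
    """Build a registered backbone.  ``spec`` is a name, a dict with a
    ``name`` key plus constructor kwargs, or an already built instance."""
    if isinstance(spec, Backbone):
        return spec
    if isinstance(spec, str):
        spec = {"name": spec}
    kwargs = {k: v for k, v in spec.items() if k != "name"}
    kwargs.setdefault("out_channels", out_channels)
    kwargs.setdefault("seed", seed)
    name = spec["name"]
    if name not in BACKBONES:
        raise KeyError(f"unknown backbone {name!r}; registered: {sorted(BACKBONES)}")
    return BACKBONES[name](**kwargs)


def extract_feature_maps(volume: np.ndarray, backbone_spec="small_cnn",
                         out_channels: int = 12, seed: int = 0) -> FeatureMap:
    """Run one normalized volume (D, H, W) through a backbone.

    Deterministic given the backbone seed; the realized output shape matches
    the backbone's declared ``output_shape``.
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3:
        raise ValueError(f"volume must be 3-D (D,H,W), got {volume.shape}")
    if not np.all(np.isfinite(volume)):
        raise ValueError("volume contains non-finite values")
    backbone = build_backbone(backbone_spec, out_channels=out_channels, seed=seed)
    out = backbone(Tensor(volume[None, None]))
    fm = FeatureMap(out.data[0])
    declared = backbone.output_shape(volume.shape)
    if fm.shape != tuple(declared):
        raise AssertionError(
            f"backbone shape contract violated: declared {declared}, got {fm.shape}"
        )
    return fm
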