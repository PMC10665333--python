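"""Lateral connection: fast-pathway motion features into the spatial pathway.

Three steps, applied after every stage: a time-strided 3D convolution
matches the fast pathway's frame count to the spatial pathway's (stride
``alpha`` in time, identity in space), a 3D squeeze-and-excitation block
reweights the downsampled channels from globally pooled statistics, and the
result is concatenated channel-wise onto the spatial-pathway features
(spatial channels first).  The transfer is one-directional: fast -> X3D.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

from .conv_blocks import validate_feature_map
from .exceptions import ConfigurationError, InvalidSpecError
from .nn import Conv3d, Linear, Module, ReLU, Sequential, ShapeError, Sigmoid, Tensor, concat

__all__ = [
    "LateralSpec",
    "TemporalDownsample",
    "SqueezeExcite3d",
    "LateralConnection",
    "temporal_downsample",
    "se3d_reweight",
    "fuse",
]


@dataclass(frozen=True)
class LateralSpec:
    """Lateral-convolution geometry and SE squeeze ratio.

    Defaults follow the time-strided lateral convention of two-pathway
    networks: kernel (5,1,1), stride (alpha,1,1), padding (2,0,0), and
    ``out_channels = 2 * C_fast``.
    """

    in_channels: int
    out_channels: int
    alpha: int = 4
    kernel: tuple[int, int, int] = (5, 1, 1)
    padding: tuple[int, int, int] = (2, 0, 0)
    se_ratio: int = 16

    def __post_init__(self):
        if self.in_channels < 1 or self.out_channels < 1:
            raise InvalidSpecError(f"channel extents must be >= 1: {self}")
        if self.alpha < 1:
            raise InvalidSpecError(f"temporal stride (alpha) must be >= 1: {self.alpha}")
        if self.se_ratio < 1:
            raise InvalidSpecError(f"se_ratio must be >= 1: {self.se_ratio}")

    @property
    def stride(self) -> tuple[int, int, int]:
        return (self.alpha, 1, 1)

    def to_dict(self) -> dict:
        return asdict(self)


class TemporalDownsample(Module):
    """Time-strided 3D convolution aligning fast-pathway T with X3D T."""

    def __init__(self, spec: LateralSpec):
        super().__init__()
        self.spec = spec
        self.conv = Conv3d(
            spec.in_channels,
            spec.out_channels,
            spec.kernel,
            stride=spec.stride,
            padding=spec.padding,
            bias=True,
        )

    def forward(self, x: Tensor) -> Tensor:
        validate_feature_map(x, "fast features")
        t = x.shape[1]
        if t % self.spec.alpha:
            raise ConfigurationError(
                f"fast-pathway T={t} is not divisible by temporal stride "
                f"alpha={self.spec.alpha}"
            )
        return self.conv(x)

    def identity_init(self) -> "TemporalDownsample":
        """Configure the kernel as an identity map (requires 1x1x1, C->C, alpha=1)."""
        if (
            self.spec.kernel != (1, 1, 1)
            or self.spec.alpha != 1
            or self.spec.in_channels != self.spec.out_channels
        ):
            raise ConfigurationError("identity init needs a 1x1x1, C->C, alpha=1 spec")
        w = self.conv.weight.data
        w[:] = 0.0
        for c in range(self.spec.in_channels):
            w[c, c, 0, 0, 0] = 1.0
        self.conv.bias.data[:] = 0.0
        return self


class SqueezeExcite3d(Module):
    """Channel gates from globally pooled (T,H,W) statistics, sigmoid in (0,1)."""

    def __init__(self, channels: int, se_ratio: int = 16):
        super().__init__()
        if se_ratio < 1:
            raise InvalidSpecError(f"se_ratio must be >= 1, got {se_ratio}")
        squeezed = max(1, channels // se_ratio)
        self.channels = channels
        self.gate = Sequential(
            Linear(channels, squeezed),
            ReLU(),
            Linear(squeezed, channels),
            Sigmoid(),
        )

    def gates(self, x: Tensor) -> Tensor:
        pooled = x.mean(axis=(1, 3, 4))                # (N, C)
        return self.gate(pooled)

    def forward(self, x: Tensor) -> Tensor:
        validate_feature_map(x)
        n, _, c, _, _ = x.shape
        if c != self.channels:
            raise ShapeError(f"SE block expects {self.channels} channels, got {x.shape}")
        g = self.gates(x).reshape(n, 1, c, 1, 1)
        return x * g


class LateralConnection(Module):
    """Downsample -> SE reweight -> channel concatenation (X3D channels first)."""

    def __init__(self, spec: LateralSpec):
        super().__init__()
        self.spec = spec
        self.down = TemporalDownsample(spec)
        self.se = SqueezeExcite3d(spec.out_channels, spec.se_ratio)

    def transfer(self, fast_feat: Tensor) -> Tensor:
        return self.se(self.down(fast_feat))

    def forward(self, x3d_feat: Tensor, fast_feat: Tensor) -> Tensor:
        return fuse_features(x3d_feat, self.transfer(fast_feat))


def fuse_features(x3d_feat: Tensor, lateral_feat: Tensor) -> Tensor:
    """Concatenate along channels after checking N, T, H, W agreement."""
    validate_feature_map(x3d_feat, "x3d features")
    validate_feature_map(lateral_feat, "lateral features")
    a, b = x3d_feat.shape, lateral_feat.shape
    for axis, name in ((0, "N"), (1, "T"), (3, "H"), (4, "W")):
        if a[axis] != b[axis]:
            raise ShapeError(
                f"lateral fusion extent mismatch on axis {name}: "
                f"x3d {a} vs lateral {b}"
            )
    return concat([x3d_feat, lateral_feat], axis=2)


# functional forms ----------------------------------------------------------


def temporal_downsample(fast_feat: Tensor, spec: LateralSpec,
                        module: TemporalDownsample | None = None) -> Tensor:
    return (module or TemporalDownsample(spec))(fast_feat)


def se3d_reweight(feat: Tensor, se_ratio: int = 16,
                  module: SqueezeExcite3d | None = None) -> Tensor:
    return (module or SqueezeExcite3d(feat.shape[2], se_ratio))(feat)


def fuse(x3d_feat: Tensor, fast_feat: Tensor, spec: LateralSpec,
         module: LateralConnection | None = None) -> Tensor:
    return (module or LateralConnection(spec))(x3d_feat, fast_feat)
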