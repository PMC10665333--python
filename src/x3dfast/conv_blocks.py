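"""Parameterized 3D convolution building blocks.

Three core convolution styles are provided, matching the ablation arms of
the behavior-recognition architecture:

* plain ``t x d x d`` 3D convolution;
* depthwise-separable 3D convolution (per-channel 3x3x3 + 1x1x1 pointwise),
  the default core of the spatial (X3D) pathway;
* R(2+1)D factorized convolution (1xdxd spatial followed by tx1x1 temporal),
  the default core of the fast pathway, with the intermediate channel count
  solved so the factorized pair carries the same number of weights as the
  full 3D kernel it replaces.

All blocks consume and produce (N, T, C, H, W) volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .exceptions import InvalidSpecError
from .nn import BatchNorm, Conv3d, Module, ReLU, Sequential, ShapeError, Tensor

__all__ = [
    "R2Plus1DSpec",
    "ConvGroupSpec",
    "solve_mid_channels",
    "build_r2plus1d",
    "build_depthwise_separable_3d",
    "R2Plus1DConv",
    "DepthwiseSeparableConv3d",
    "ResidualGroup",
    "validate_feature_map",
    "conv_weight_count",
]


def validate_feature_map(x: Tensor | np.ndarray, name: str = "input") -> None:
    """Check the (N,T,C,H,W) feature-volume contract: 5 axes, finite values."""
    data = x.data if isinstance(x, Tensor) else np.asarray(x)
    if data.ndim != 5:
        raise ShapeError(
            f"{name} must be a 5-axis (N,T,C,H,W) volume, got shape {data.shape}"
        )
    if min(data.shape) < 1:
        raise ShapeError(f"{name} has a zero extent: {data.shape}")
    if not np.isfinite(data).all():
        raise ValueError(f"{name} contains non-finite values")


def conv_weight_count(module: Module) -> int:
    """Total kernel-weight count of all Conv3d layers below ``module`` (no bias/norm)."""
    return sum(m.weight_count() for m in module.modules() if isinstance(m, Conv3d))


# ---------------------------------------------------------------------------
# R(2+1)D factorization
# ---------------------------------------------------------------------------


def solve_mid_channels(t: int, d: int, n_in: int, n_out: int) -> int:
    """Intermediate channel count matching the full-3D parameter budget.

    A ``t x d x d`` kernel mapping ``n_in -> n_out`` channels has
    ``n_in * t * d^2 * n_out`` weights.  The factorized pair (1xdxd then
    tx1x1) with ``m`` intermediate channels has
    ``n_in * d^2 * m + m * t * n_out`` weights.  Equating the two and
    flooring gives the largest integer ``m`` whose factorized count does not
    exceed the 3D count; degenerate configurations are clamped to 1.
    """
    for name, v in (("t", t), ("d", d), ("n_in", n_in), ("n_out", n_out)):
        if not isinstance(v, (int, np.integer)) or v < 1:
            raise InvalidSpecError(f"{name} must be a positive integer, got {v!r}")
    m = (t * d * d * n_in * n_out) // (d * d * n_in + t * n_out)
    return max(1, int(m))


@dataclass(frozen=True)
class R2Plus1DSpec:
    """Factorized-convolution description: kernel extents, channels, solved mid width."""

    t: int
    d: int
    n_in: int
    n_out: int
    m_mid: int = field(default=0)

    def __post_init__(self):
        for name in ("t", "d", "n_in", "n_out"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 1:
                raise InvalidSpecError(f"{name} must be a positive integer, got {v!r}")
        if self.m_mid == 0:
            object.__setattr__(
                self, "m_mid", solve_mid_channels(self.t, self.d, self.n_in, self.n_out)
            )
        elif self.m_mid < 1:
            raise InvalidSpecError(f"m_mid must be >= 1, got {self.m_mid}")

    @property
    def factorized_params(self) -> int:
        return self.n_in * self.d**2 * self.m_mid + self.m_mid * self.t * self.n_out

    @property
    def full3d_params(self) -> int:
        return self.n_in * self.t * self.d**2 * self.n_out


class R2Plus1DConv(Module):
    """1xdxd spatial conv -> BN -> ReLU -> tx1x1 temporal conv.

    The internal nonlinearity is the extra one the factorization buys over a
    single 3D convolution; a trailing BN+ReLU is appended only when the unit
    is built standalone (residual groups supply their own).
    """

    def __init__(self, spec: R2Plus1DSpec, stride=(1, 1, 1), bias: bool = False):
        super().__init__()
        self.spec = spec
        st, sh, sw = nn._triple(stride)
        self.spatial = Conv3d(
            spec.n_in, spec.m_mid, (1, spec.d, spec.d), stride=(1, sh, sw), bias=bias
        )
        self.bn_mid = BatchNorm(spec.m_mid)
        self.act_mid = ReLU()
        self.temporal = Conv3d(
            spec.m_mid, spec.n_out, (spec.t, 1, 1), stride=(st, 1, 1), bias=bias
        )

    def forward(self, x: Tensor) -> Tensor:
        return self.temporal(self.act_mid(self.bn_mid(self.spatial(x))))

    def weight_count(self) -> int:
        return self.spatial.weight_count() + self.temporal.weight_count()


class DepthwiseSeparableConv3d(Module):
    """Per-channel (grouped) 3D convolution followed by 1x1x1 pointwise mixing."""

    def __init__(self, c_in: int, c_out: int, kernel=(3, 3, 3), stride=(1, 1, 1),
                 bias: bool = False):
        super().__init__()
        if c_in < 1 or c_out < 1:
            raise InvalidSpecError(f"channel extents must be >= 1, got {c_in}->{c_out}")
        self.depthwise = Conv3d(c_in, c_in, kernel, stride=stride, groups=c_in, bias=bias)
        self.pointwise = Conv3d(c_in, c_out, (1, 1, 1), bias=bias)

    def forward(self, x: Tensor) -> Tensor:
        return self.pointwise(self.depthwise(x))

    def weight_count(self) -> int:
        return self.depthwise.weight_count() + self.pointwise.weight_count()


def build_r2plus1d(spec: R2Plus1DSpec, stride=(1, 1, 1), standalone: bool = True,
                   bias: bool = False) -> Module:
    """Build an R(2+1)D unit; standalone units carry their trailing BN+ReLU."""
    core = R2Plus1DConv(spec, stride=stride, bias=bias)
    if standalone:
        return Sequential(core, BatchNorm(spec.n_out), ReLU())
    return core


def build_depthwise_separable_3d(c_in: int, c_out: int, kernel=(3, 3, 3),
                                 stride=(1, 1, 1), bias: bool = False) -> Module:
    return DepthwiseSeparableConv3d(c_in, c_out, kernel, stride=stride, bias=bias)


# ---------------------------------------------------------------------------
# residual convolution group
# ---------------------------------------------------------------------------

CONV_STYLES = ("plain", "depthwise_separable", "r2plus1d")


@dataclass(frozen=True)
class ConvGroupSpec:
    """Residual-group description: channels, kernel extents, stride and core style."""

    c_in: int
    c_out: int
    temporal_kernel: int = 3
    spatial_kernel: int = 3
    stride: tuple[int, int] = (1, 1)  # (time, space)
    conv_style: str = "plain"

    def __post_init__(self):
        if self.c_in < 1 or self.c_out < 1:
            raise InvalidSpecError(f"channel extents must be >= 1: {self}")
        if any(s < 1 for s in self.stride):
            raise InvalidSpecError(f"stride entries must be >= 1: {self.stride}")
        if self.conv_style not in CONV_STYLES:
            raise InvalidSpecError(
                f"conv_style must be one of {CONV_STYLES}, got {self.conv_style!r}"
            )


def _core_conv(spec: ConvGroupSpec, c_in: int, c_out: int, stride) -> Module:
    kernel = (spec.temporal_kernel, spec.spatial_kernel, spec.spatial_kernel)
    if spec.conv_style == "depthwise_separable":
        return DepthwiseSeparableConv3d(c_in, c_out, kernel, stride=stride)
    if spec.conv_style == "r2plus1d":
        r2spec = R2Plus1DSpec(spec.temporal_kernel, spec.spatial_kernel, c_in, c_out)
        return R2Plus1DConv(r2spec, stride=stride)
    return Conv3d(c_in, c_out, kernel, stride=stride)


class ResidualGroup(Module):
    """Two core convolutions with a shortcut: ``F(x) + shortcut(x)``.

    The residual branch is conv -> BN -> ReLU -> conv -> BN; there is no
    post-sum activation, so a zero residual branch passes the input through
    untouched.  When stride is 1 and channel extents match, the shortcut is
    the identity; otherwise a 1x1x1 projection (+BN) aligns extents.
    """

    def __init__(self, spec: ConvGroupSpec):
        super().__init__()
        self.spec = spec
        st, ss = spec.stride
        stride3 = (st, ss, ss)
        self.conv1 = _core_conv(spec, spec.c_in, spec.c_out, stride3)
        self.bn1 = BatchNorm(spec.c_out)
        self.act = ReLU()
        self.conv2 = _core_conv(spec, spec.c_out, spec.c_out, (1, 1, 1))
        self.bn2 = BatchNorm(spec.c_out)
        if spec.c_in == spec.c_out and stride3 == (1, 1, 1):
            self.projection = None
        else:
            self.projection = Sequential(
                Conv3d(spec.c_in, spec.c_out, (1, 1, 1), stride=stride3),
                BatchNorm(spec.c_out),
            )

    def forward(self, x: Tensor) -> Tensor:
        validate_feature_map(x)
        if x.shape[2] != self.spec.c_in:
            raise ShapeError(
                f"residual group expects {self.spec.c_in} channels, "
                f"input has shape {x.shape}"
            )
        branch = self.bn2(self.conv2(self.act(self.bn1(self.conv1(x)))))
        shortcut = x if self.projection is None else self.projection(x)
        return branch + shortcut

    def zero_init_residual(self) -> "ResidualGroup":
        """Zero the closing BN scale so the group starts as (a projection of) identity."""
        self.bn2.weight.data[:] = 0.0
        return self


def residual_group_forward(x: Tensor, group: ResidualGroup) -> Tensor:
    return group(x)
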