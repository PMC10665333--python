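"""Three-branch action attention: spatial-temporal, channel and motion excitation.

Each branch produces a sigmoid mask in (0, 1) and rescales the input through
the residual form ``Y = X + X * Mask``, so a branch can only amplify (by at
most 2x) and never suppress a nonnegative activation.  The branches gate
along different axes:

* STE — the input is collapsed to one channel, a single 3D convolution
  scores every (t, h, w) cell, and the mask broadcasts over channels;
* CE — global spatial pooling, channel squeeze by ratio ``r``, a 1D temporal
  convolution, channel expansion; the mask broadcasts over space;
* ME — channel-squeezed adjacent-frame differences (a 2D convolution on the
  leading frame minus the trailing frame), zero-padded at the last slot to
  restore the clip length, then pooled and expanded to a channel mask.

The combined action module averages the three branch outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .conv_blocks import validate_feature_map
from .exceptions import InvalidSpecError, MotionUndefinedError
from .nn import Conv3d, Module, Tensor, concat

__all__ = [
    "ExcitationBranchConfig",
    "STEBranch",
    "CEBranch",
    "MEBranch",
    "ActionModule",
    "ste_branch",
    "ce_branch",
    "me_branch",
    "action_module",
]


@dataclass(frozen=True)
class ExcitationBranchConfig:
    """Attention-branch hyperparameters.

    ``r`` is the channel compression ratio (squeezed width = ceil(C/r),
    clamped to 1).  Kernel extents must be odd so symmetric padding
    preserves extents.
    """

    r: int = 16
    ste_kernel: int = 3
    ce_temporal_kernel: int = 3
    me_spatial_kernel: int = 3
    combine: str = "mean"  # or "sum"

    def __post_init__(self):
        if self.r < 1:
            raise InvalidSpecError(f"compression ratio must be >= 1, got {self.r}")
        for name in ("ste_kernel", "ce_temporal_kernel", "me_spatial_kernel"):
            k = getattr(self, name)
            if k < 1 or k % 2 == 0:
                raise InvalidSpecError(f"{name} must be odd and positive, got {k}")
        if self.combine not in ("mean", "sum"):
            raise InvalidSpecError(f"combine must be 'mean' or 'sum', got {self.combine!r}")

    def squeezed(self, channels: int) -> int:
        return max(1, math.ceil(channels / self.r))


class STEBranch(Module):
    """Spatial-temporal excitation: a one-channel (t,h,w) saliency mask."""

    def __init__(self, channels: int, cfg: ExcitationBranchConfig):
        super().__init__()
        self.cfg = cfg
        k = cfg.ste_kernel
        self.score = Conv3d(1, 1, (k, k, k), bias=True)

    def forward(self, x: Tensor) -> Tensor:
        validate_feature_map(x)
        pooled = x.mean(axis=2, keepdims=True)          # (N,T,1,H,W)
        mask = self.score(pooled).sigmoid()             # (N,T,1,H,W)
        return x + x * mask

    def mask(self, x: Tensor) -> Tensor:
        return self.score(x.mean(axis=2, keepdims=True)).sigmoid()


class CEBranch(Module):
    """Channel excitation: squeeze, temporal 1D convolution, expand."""

    def __init__(self, channels: int, cfg: ExcitationBranchConfig):
        super().__init__()
        self.cfg = cfg
        c_r = cfg.squeezed(channels)
        self.squeeze = Conv3d(channels, c_r, (1, 1, 1), bias=True)
        self.temporal = Conv3d(c_r, c_r, (cfg.ce_temporal_kernel, 1, 1), bias=True)
        self.expand = Conv3d(c_r, channels, (1, 1, 1), bias=True)

    def mask(self, x: Tensor) -> Tensor:
        pooled = x.mean(axis=(3, 4), keepdims=True)     # (N,T,C,1,1)
        f = self.expand(self.temporal(self.squeeze(pooled)))
        return f.sigmoid()                              # (N,T,C,1,1)

    def forward(self, x: Tensor) -> Tensor:
        validate_feature_map(x)
        return x + x * self.mask(x)


class MEBranch(Module):
    """Motion excitation from channel-squeezed adjacent-frame differences."""

    def __init__(self, channels: int, cfg: ExcitationBranchConfig):
        super().__init__()
        self.cfg = cfg
        c_r = cfg.squeezed(channels)
        k = cfg.me_spatial_kernel
        self.squeeze = Conv3d(channels, c_r, (1, 1, 1), bias=True)
        self.motion = Conv3d(c_r, c_r, (1, k, k), bias=True)  # frame-wise 2D conv
        self.expand = Conv3d(c_r, channels, (1, 1, 1), bias=True)

    def motion_volume(self, x: Tensor) -> Tensor:
        """Adjacent-frame differences, zero-padded at the final slot: (N,T,C/r,H,W)."""
        n, t, _, h, w = x.shape
        if t < 2:
            raise MotionUndefinedError(
                "motion excitation needs T >= 2; bypass the ME branch for "
                "single-frame inputs"
            )
        f_r = self.squeeze(x)                           # (N,T,C/r,H,W)
        diffs = self.motion(f_r)[:, 1:] - f_r[:, : t - 1]
        zero = Tensor(np.zeros((n, 1) + diffs.shape[2:], dtype=diffs.dtype))
        return concat([diffs, zero], axis=1)            # (N,T,C/r,H,W)

    def mask(self, x: Tensor) -> Tensor:
        pooled = self.motion_volume(x).mean(axis=(3, 4), keepdims=True)
        return self.expand(pooled).sigmoid()            # (N,T,C,1,1)

    def forward(self, x: Tensor) -> Tensor:
        validate_feature_map(x)
        return x + x * self.mask(x)


class ActionModule(Module):
    """Average (or sum) of the three excitation-branch outputs."""

    def __init__(self, channels: int, cfg: ExcitationBranchConfig | None = None):
        super().__init__()
        self.cfg = cfg or ExcitationBranchConfig()
        self.ste = STEBranch(channels, self.cfg)
        self.ce = CEBranch(channels, self.cfg)
        self.me = MEBranch(channels, self.cfg)

    def forward(self, x: Tensor) -> Tensor:
        validate_feature_map(x)
        combined = self.ste(x) + self.ce(x) + self.me(x)
        if self.cfg.combine == "mean":
            return combined * (1.0 / 3.0)
        return combined


# functional forms ----------------------------------------------------------


def ste_branch(x: Tensor, branch: STEBranch) -> Tensor:
    return branch(x)


def ce_branch(x: Tensor, branch: CEBranch) -> Tensor:
    return branch(x)


def me_branch(x: Tensor, branch: MEBranch) -> Tensor:
    return branch(x)


def action_module(x: Tensor, module: ActionModule) -> Tensor:
    return module(x)
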