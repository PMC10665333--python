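"""The two feature pathways and dual-rate clip sampling.

The spatial (X3D) pathway runs four stages of residual convolution groups —
3, 5, 11 and 7 groups in the full profile — with a depthwise-separable core
and an action-attention module after every group.  The fast pathway mirrors
the stage layout with far fewer channels (ratio ``beta``), an R(2+1)D core,
and ``alpha`` times more frames; it never downsamples time, so every stage
keeps the input frame count.  Spatial downsampling (stride 2) happens at the
stem and at stages 2-4 of both pathways.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .action_attention import ActionModule, ExcitationBranchConfig
from .conv_blocks import ConvGroupSpec, ResidualGroup, validate_feature_map
from .exceptions import ConfigurationError, InvalidSpecError
from .nn import BatchNorm, Conv3d, Module, ModuleList, ReLU, ShapeError, Tensor

__all__ = [
    "PathwayProfile",
    "Pathway",
    "sample_dual_rate",
    "dual_rate_indices",
    "x3d_pathway_forward",
    "fast_pathway_forward",
    "full_x3d_profile",
    "tiny_x3d_profile",
    "fast_profile_from",
]

FULL_STAGE_GROUPS = (3, 5, 11, 7)


@dataclass(frozen=True)
class PathwayProfile:
    """Architectural profile of one pathway."""

    stage_groups: tuple[int, int, int, int]
    stage_channels: tuple[int, int, int, int]
    stem_channels: int
    t_frames: int
    spatial_strides: tuple[int, int, int, int] = (1, 2, 2, 2)
    attention_enabled: bool = False
    conv_style: str = "depthwise_separable"
    in_channels: int = 3

    def __post_init__(self):
        for name in ("stage_groups", "stage_channels", "spatial_strides"):
            v = tuple(getattr(self, name))
            object.__setattr__(self, name, v)
            if len(v) != 4 or any(int(e) < 1 for e in v):
                raise InvalidSpecError(f"{name} must be 4 positive integers, got {v}")
        if self.t_frames < 1 or self.stem_channels < 1:
            raise InvalidSpecError("t_frames and stem_channels must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PathwayProfile":
        return cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in d.items()})


def full_x3d_profile(attention: bool = True) -> PathwayProfile:
    """The full spatial-pathway profile: 3/5/11/7 groups, widths 24/48/96/192."""
    return PathwayProfile(
        stage_groups=FULL_STAGE_GROUPS,
        stage_channels=(24, 48, 96, 192),
        stem_channels=24,
        t_frames=8,
        attention_enabled=attention,
        conv_style="depthwise_separable",
    )


def tiny_x3d_profile(attention: bool = True) -> PathwayProfile:
    """Desk-scale profile used by the synthetic-training harness and tests."""
    return PathwayProfile(
        stage_groups=(1, 1, 2, 1),
        stage_channels=(8, 16, 24, 32),
        stem_channels=8,
        t_frames=4,
        attention_enabled=attention,
        conv_style="depthwise_separable",
    )


def fast_profile_from(
    x3d: PathwayProfile,
    alpha: int = 4,
    beta: float = 1 / 8,
    conv_style: str = "r2plus1d",
) -> PathwayProfile:
    """Derive the fast-pathway profile: ``round(beta)``-scaled widths, ``alpha``x frames."""
    if alpha < 1 or int(alpha) != alpha:
        raise InvalidSpecError(f"alpha must be a positive integer, got {alpha}")
    if not 0 < beta <= 1:
        raise InvalidSpecError(f"beta must be in (0, 1], got {beta}")
    widths = tuple(max(1, round(beta * c)) for c in x3d.stage_channels)
    return PathwayProfile(
        stage_groups=x3d.stage_groups,
        stage_channels=widths,
        stem_channels=max(1, round(beta * x3d.stem_channels)),
        t_frames=int(alpha) * x3d.t_frames,
        spatial_strides=x3d.spatial_strides,
        attention_enabled=False,
        conv_style=conv_style,
        in_channels=x3d.in_channels,
    )


# ---------------------------------------------------------------------------
# clip sampling
# ---------------------------------------------------------------------------


def dual_rate_indices(n_frames: int, t_x3d: int, alpha: int) -> tuple[np.ndarray, np.ndarray]:
    """Frame indices the two pathways sample from an ``n_frames`` clip.

    Returns ``(x3d_indices, fast_indices)``; indices wrap modulo ``n_frames``
    when the clip is shorter than the fast sampling grid.
    """
    if n_frames < 1:
        raise ValueError("cannot sample from an empty clip")
    if t_x3d < 1 or alpha < 1:
        raise InvalidSpecError("t_x3d and alpha must be >= 1")
    n_fast = t_x3d * alpha
    n = n_frames if n_frames >= n_fast else n_frames * (-(-n_fast // n_frames))
    fast_idx = ((np.arange(n_fast) * n) // n_fast) % n_frames
    return fast_idx[::alpha].copy(), fast_idx


def sample_dual_rate(
    frames: np.ndarray, t_x3d: int, alpha: int
) -> tuple[np.ndarray, np.ndarray]:
    """Sample one clip for each pathway from a decoded frame stack.

    The fast clip takes ``alpha * t_x3d`` uniformly spaced frames (strictly
    increasing indices when enough frames exist; shorter clips are looped);
    the spatial clip takes every ``alpha``-th of those, so the two clips stay
    temporally aligned.  ``frames`` is indexed along axis 0.
    """
    frames = np.asarray(frames)
    x3d_idx, fast_idx = dual_rate_indices(frames.shape[0], t_x3d, alpha)
    return frames[x3d_idx], frames[fast_idx]


# ---------------------------------------------------------------------------
# pathway module
# ---------------------------------------------------------------------------


class Pathway(Module):
    """Stem plus four stages of residual groups (optionally attention-gated).

    ``extra_in_channels`` widens the input of stages 2-4 to accept features
    concatenated by lateral fusion; it is all zeros for a standalone pathway.
    """

    def __init__(
        self,
        profile: PathwayProfile,
        extra_in_channels: tuple[int, int, int, int] = (0, 0, 0, 0),
        attention_cfg: ExcitationBranchConfig | None = None,
    ):
        super().__init__()
        self.profile = profile
        self.extra_in_channels = tuple(extra_in_channels)
        self.stem = Conv3d(
            profile.in_channels, profile.stem_channels, (3, 3, 3), stride=(1, 2, 2)
        )
        self.stem_bn = BatchNorm(profile.stem_channels)
        self.stem_act = ReLU()
        cfg = attention_cfg or ExcitationBranchConfig()
        self.stages = ModuleList()
        self.attention = ModuleList()
        c_prev = profile.stem_channels
        for i in range(4):
            c_in = c_prev + self.extra_in_channels[i]
            c_out = profile.stage_channels[i]
            blocks = ModuleList()
            for g in range(profile.stage_groups[i]):
                spec = ConvGroupSpec(
                    c_in=c_in if g == 0 else c_out,
                    c_out=c_out,
                    stride=(1, profile.spatial_strides[i]) if g == 0 else (1, 1),
                    conv_style=profile.conv_style,
                )
                blocks.append(ResidualGroup(spec))
            self.stages.append(_Stage(blocks))
            if profile.attention_enabled:
                gates = ModuleList(
                    ActionModule(c_out, cfg) for _ in range(profile.stage_groups[i])
                )
            else:
                gates = ModuleList()
            self.attention.append(_GateList(gates))
            c_prev = c_out

    @property
    def out_channels(self) -> tuple[int, int, int, int]:
        return self.profile.stage_channels

    def forward_stem(self, clip: Tensor) -> Tensor:
        validate_feature_map(clip, "clip")
        if clip.shape[1] != self.profile.t_frames:
            raise ShapeError(
                f"pathway expects T={self.profile.t_frames}, clip has shape {clip.shape}"
            )
        return self.stem_act(self.stem_bn(self.stem(clip)))

    def forward_stage(self, i: int, x: Tensor) -> Tensor:
        gates = self.attention[i].gates
        for g, block in enumerate(self.stages[i].blocks):
            x = block(x)
            if gates:
                x = gates[g](x)
        return x

    def forward(self, clip: Tensor) -> list[Tensor]:
        """Run all stages without lateral fusion; returns the 4 stage outputs."""
        if any(self.extra_in_channels):
            raise ConfigurationError(
                "pathway built for lateral fusion cannot run standalone"
            )
        x = self.forward_stem(clip)
        outs: list[Tensor] = []
        for i in range(4):
            x = self.forward_stage(i, x)
            outs.append(x)
        return outs

    def num_groups(self) -> int:
        return sum(len(s.blocks) for s in self.stages)


class _Stage(Module):
    def __init__(self, blocks: ModuleList):
        super().__init__()
        self.blocks = blocks


class _GateList(Module):
    def __init__(self, gates: ModuleList):
        super().__init__()
        self.gates = gates


def x3d_pathway_forward(clip: Tensor, profile: PathwayProfile,
                        pathway: Pathway | None = None) -> list[Tensor]:
    """Run a standalone spatial pathway; returns the four stage outputs."""
    pw = pathway or Pathway(profile)
    return pw(clip)


def fast_pathway_forward(clip: Tensor, profile: PathwayProfile,
                         pathway: Pathway | None = None) -> list[Tensor]:
    """Run a standalone fast pathway; returns the four stage outputs."""
    pw = pathway or Pathway(profile)
    return pw(clip)
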