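"""Full two-pathway model: pathways + lateral fusion + predictor.

Also home to the training loss (mean cross-entropy over one-hot labels),
the top-1 accuracy metric, gradient-weighted class-activation maps, and
checkpoint IO.  The three ablation switches — lateral fusion, R(2+1)D fast
cores, action attention — reproduce the architecture's ablation arms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .exceptions import ConfigurationError, NotTrainedError
from .lateral_fusion import LateralConnection, LateralSpec
from .nn import (
    Dropout,
    Linear,
    Module,
    ModuleList,
    ReLU,
    ShapeError,
    Tensor,
    concat,
)
from .pathways import Pathway, PathwayProfile, fast_profile_from, full_x3d_profile, tiny_x3d_profile

__all__ = [
    "ModelConfig",
    "X3DFast",
    "CamResult",
    "cross_entropy",
    "top1",
    "compute_cam",
    "save_checkpoint",
    "load_checkpoint",
]


@dataclass(frozen=True)
class ModelConfig:
    """Full architectural profile, including the three ablation switches."""

    x3d_profile: PathwayProfile
    alpha: int = 4
    beta: float = 1 / 8
    num_classes: int = 4
    predictor_hidden: int = 256
    predictor_dropout: float = 0.5
    lateral_kernel: tuple[int, int, int] = (5, 1, 1)
    lateral_padding: tuple[int, int, int] = (2, 0, 0)
    se_ratio: int = 16
    use_lateral: bool = True
    use_r2plus1d: bool = True
    use_action: bool = True

    def __post_init__(self):
        if self.num_classes < 2:
            raise ConfigurationError(f"need >= 2 classes, got {self.num_classes}")

    @property
    def fast_profile(self) -> PathwayProfile:
        return fast_profile_from(
            self.x3d_profile,
            alpha=self.alpha,
            beta=self.beta,
            conv_style="r2plus1d" if self.use_r2plus1d else "plain",
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["x3d_profile"] = self.x3d_profile.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        prof = d.pop("x3d_profile")
        if isinstance(prof, dict):
            prof = PathwayProfile.from_dict(prof)
        for key in ("lateral_kernel", "lateral_padding"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(x3d_profile=prof, **d)

    @classmethod
    def full(cls, **overrides) -> "ModelConfig":
        cfg = dict(x3d_profile=full_x3d_profile(attention=True), alpha=4, beta=1 / 8)
        cfg.update(overrides)
        return cls(**cfg)

    @classmethod
    def tiny(cls, **overrides) -> "ModelConfig":
        cfg = dict(x3d_profile=tiny_x3d_profile(attention=True), alpha=2, beta=1 / 4)
        cfg.update(overrides)
        return cls(**cfg)


class X3DFast(Module):
    """Two-pathway behavior classifier producing M logits per clip pair."""

    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        x3d_prof = config.x3d_profile
        if not config.use_action:
            x3d_prof = PathwayProfile(**{**x3d_prof.to_dict(), "attention_enabled": False})
        fast_prof = config.fast_profile
        fast_ch = fast_prof.stage_channels

        if config.use_lateral:
            lat_out = tuple(2 * c for c in fast_ch)
            extra = (0, lat_out[0], lat_out[1], lat_out[2])
            self.laterals = ModuleList(
                LateralConnection(
                    LateralSpec(
                        in_channels=fast_ch[i],
                        out_channels=lat_out[i],
                        alpha=config.alpha,
                        kernel=config.lateral_kernel,
                        padding=config.lateral_padding,
                        se_ratio=config.se_ratio,
                    )
                )
                for i in range(4)
            )
            x3d_final_ch = x3d_prof.stage_channels[3] + lat_out[3]
        else:
            extra = (0, 0, 0, 0)
            self.laterals = ModuleList()
            x3d_final_ch = x3d_prof.stage_channels[3]

        self.x3d = Pathway(x3d_prof, extra_in_channels=extra)
        self.fast = Pathway(fast_prof)
        predictor_in = x3d_final_ch + fast_ch[3]
        self.fc1 = Linear(predictor_in, config.predictor_hidden)
        self.fc_act = ReLU()
        self.dropout = Dropout(config.predictor_dropout)
        self.fc2 = Linear(config.predictor_hidden, config.num_classes)
        self.trained = False
        self._cam_features: list[Tensor] | None = None

    # -- forward ------------------------------------------------------------
    def forward(self, x3d_clip, fast_clip, capture_cam: bool = False) -> Tensor:
        x3d_t = x3d_clip if isinstance(x3d_clip, Tensor) else Tensor(x3d_clip)
        fast_t = fast_clip if isinstance(fast_clip, Tensor) else Tensor(fast_clip)
        x = self.x3d.forward_stem(x3d_t)
        f = self.fast.forward_stem(fast_t)
        fused: list[Tensor] = []
        for i in range(4):
            f = self.fast.forward_stage(i, f)
            x = self.x3d.forward_stage(i, x)
            if self.laterals:
                x = self.laterals[i](x, f)
            fused.append(x)
        self._cam_features = fused if capture_cam else None
        x_pool = x.mean(axis=(1, 3, 4))    # (N, C_x3d_final)
        f_pool = f.mean(axis=(1, 3, 4))    # (N, C_fast_final)
        h = self.dropout(self.fc_act(self.fc1(concat([x_pool, f_pool], axis=1))))
        return self.fc2(h)


# ---------------------------------------------------------------------------
# loss and metric
# ---------------------------------------------------------------------------

PROB_EPS = 1e-12


def cross_entropy(probs: np.ndarray, labels_onehot: np.ndarray) -> float:
    """Mean cross-entropy ``-(1/N) sum_i sum_c y_ic log p_ic``.

    ``probs`` rows must sum to 1 within 1e-6 and ``labels_onehot`` rows must
    be exactly one-hot; probabilities are clamped at 1e-12 before the log.
    """
    p = np.asarray(probs, dtype=np.float64)
    y = np.asarray(labels_onehot, dtype=np.float64)
    if p.shape != y.shape or p.ndim != 2:
        raise ShapeError(f"probs {p.shape} and labels {y.shape} must both be (N, M)")
    row_sums = p.sum(axis=1)
    if not np.allclose(row_sums, 1.0, atol=1e-6):
        bad = int(np.argmax(np.abs(row_sums - 1.0)))
        raise ValueError(f"probability row {bad} sums to {row_sums[bad]:.8f}, not 1")
    if not (np.isin(y, (0.0, 1.0)).all() and (y.sum(axis=1) == 1.0).all()):
        raise ValueError("labels must be exactly one-hot rows")
    return float(-(y * np.log(np.clip(p, PROB_EPS, None))).sum() / p.shape[0])


def top1(predictions: np.ndarray, labels: np.ndarray) -> float:
    """Fraction of samples whose argmax score matches the true class.

    ``predictions`` is (N, M) scores (ties resolve to the lowest class
    index) or already-argmaxed (N,) indices; ``labels`` is (N,) indices or
    (N, M) one-hot.
    """
    pred = np.asarray(predictions)
    lab = np.asarray(labels)
    if pred.size == 0 or lab.size == 0:
        raise ValueError("top-1 is undefined for empty inputs")
    pred_idx = pred.argmax(axis=1) if pred.ndim == 2 else pred.astype(int)
    lab_idx = lab.argmax(axis=1) if lab.ndim == 2 else lab.astype(int)
    if pred_idx.shape != lab_idx.shape:
        raise ShapeError(f"prediction/label lengths differ: {pred_idx.shape} vs {lab_idx.shape}")
    return float((pred_idx == lab_idx).mean())


# ---------------------------------------------------------------------------
# class-activation maps
# ---------------------------------------------------------------------------


@dataclass
class CamResult:
    """Per-frame nonnegative heatmaps, max-normalized frame-wise when nonzero."""

    heatmaps: np.ndarray          # (T', H', W')
    predicted_class: int
    target_class: int
    logits: np.ndarray            # (M,)


def compute_cam(
    model: X3DFast,
    x3d_clip: np.ndarray,
    fast_clip: np.ndarray,
    target_class: int | None = None,
    upsample_to: tuple[int, int] | None = None,
    stage: int | None = None,
) -> CamResult:
    """Gradient-weighted activation map on a fused feature volume.

    Channel weights are the gradients of the target-class logit pooled over
    time and space; the heatmap is the rectified weighted channel sum per
    frame.  ``stage`` selects which fused stage output to map (0-3); the
    default is the final fused volume.  At desk scale the deep stages have
    effectively global receptive fields, so localization analyses are better
    served by an earlier stage (see ``pipeline.cam_localization_rate``).
    Requires a trained model.
    """
    if not model.trained:
        raise NotTrainedError(
            "class-activation maps require trained weights; train the model or "
            "load a checkpoint first"
        )
    model.eval()
    x3d_arr = np.asarray(x3d_clip, dtype=np.float32)
    fast_arr = np.asarray(fast_clip, dtype=np.float32)
    if x3d_arr.ndim == 4:
        x3d_arr, fast_arr = x3d_arr[None], fast_arr[None]
    logits = model.forward(x3d_arr, fast_arr, capture_cam=True)
    feature = model._cam_features[-1 if stage is None else stage]
    pred = int(logits.data[0].argmax())
    target = pred if target_class is None else int(target_class)
    score = logits[0, target]
    score.backward()
    grads = feature.grad[0]                      # (T', C, H', W')
    acts = feature.data[0]
    weights = grads.mean(axis=(0, 2, 3))         # (C,)
    heat = np.einsum("tchw,c->thw", acts, weights)
    heat = np.maximum(heat, 0.0)
    peak = heat.max(axis=(1, 2), keepdims=True)
    np.divide(heat, peak, out=heat, where=peak > 0)
    if upsample_to is not None:
        from scipy.ndimage import zoom

        # grid_mode treats heat values as cell-centered, so the peak of the
        # upsampled map stays at the source cell's center, not an image corner
        factors = (upsample_to[0] / heat.shape[1], upsample_to[1] / heat.shape[2])
        heat = np.stack(
            [zoom(h, factors, order=1, grid_mode=True, mode="nearest") for h in heat]
        )
    model._cam_features = None
    return CamResult(
        heatmaps=heat.astype(np.float64),
        predicted_class=pred,
        target_class=target,
        logits=logits.data[0].copy(),
    )


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(path, model: X3DFast, seed: int | None = None,
                    history: list[dict] | None = None) -> None:
    """Self-describing archive: config + weights + seed + metric history."""
    meta = {
        "config": model.config.to_dict(),
        "seed": seed,
        "history": history or [],
        "trained": model.trained,
    }
    arrays = {f"state/{k}": v for k, v in model.state_dict().items()}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **arrays)


def load_checkpoint(path) -> tuple[X3DFast, dict]:
    """Rebuild a model from an archive; returns (model, metadata)."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k[len("state/"):]: data[k] for k in data.files if k.startswith("state/")}
    model = X3DFast(ModelConfig.from_dict(meta["config"]))
    model.load_state_dict(state)
    model.trained = bool(meta.get("trained", True))
    model.eval()
    return model, meta
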