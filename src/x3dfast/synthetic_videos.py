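"""Deterministic simulator of labeled dairy-cow behavior clips.

The simulator does not attempt photorealism; it reproduces the statistical
structure that makes the four behaviors separable in real footage:

* ``standing`` / ``lying`` are static and differ *spatially* — a standing
  body projects as an elongated blob, a lying body as a nearly round one
  (aspect ratios differing by >= 1.5x);
* ``walking`` differs *temporally* — the same elongated body translates at
  a velocity at least twice the stationary jitter amplitude;
* ``mounting`` shows two bodies whose vertical overlap oscillates, with
  nonzero overlap in at least half the frames and brief separations.

Bodies are textured ellipses on a textured darker background.  Degradations
(illumination gain, Gaussian blur, occluding rectangles) mirror the
occlusion / blur / dim-lighting conditions of barn surveillance footage.
Per-frame foreground masks are stored alongside the frames so that
class-activation maps can be scored against ground truth — an affordance
real footage lacks.

A hand-crafted kinematic oracle (connected components, centroid motion,
shape aspect) validates that the class signal exists; it is the generator's
acceptance gate, not a learned model.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .exceptions import InvalidSpecError

__all__ = [
    "BEHAVIORS",
    "TABLE_COUNTS",
    "DURATION_RANGES",
    "SceneSpec",
    "ClipRecord",
    "generate_clip",
    "apply_degradations",
    "generate_dataset",
    "oracle_classify",
    "oracle_classify_frame",
    "dataset_checksum",
]

BEHAVIORS = ("standing", "lying", "walking", "mounting")

# per-class clip counts of the reference barn dataset, used as ratio template
TABLE_COUNTS = {"standing": 1799, "lying": 1947, "walking": 1130, "mounting": 774}

# per-class clip duration ranges in seconds (mounting takes longest)
DURATION_RANGES = {
    "standing": (1.0, 2.0),
    "lying": (1.0, 2.0),
    "walking": (1.0, 3.0),
    "mounting": (2.0, 4.0),
}

# body half-axes (major, minor) in pixels on the default 64x64 canvas
_BODY_AXES = {
    "standing": (12.0, 5.0),   # aspect 2.4
    "lying": (10.5, 9.0),      # aspect ~1.17  (>= 1.5x flatter than standing)
    "walking": (12.0, 5.0),    # same shape as standing; only the motion differs
    "mounting": (11.0, 6.0),
}

_BODY_INTENSITY = 185.0
_SECOND_BODY_INTENSITY = 150.0
_DISTRACTOR_INTENSITY = 95.0
_BACKGROUND_BASE = 55.0
_FOREGROUND_THRESHOLD = 110.0  # used by the oracle; bodies sit well above it


@dataclass(frozen=True)
class SceneSpec:
    """Everything needed to render one clip, including degradations and seed."""

    behavior: str
    canvas: tuple[int, int] = (64, 64)
    t_frames: int = 16
    fps: float = 12.5
    body_axes: tuple[float, float] | None = None
    velocity: float = 2.0            # px/frame, walking
    jitter: float = 1.0              # px, standing/lying positional noise
    overlap_amplitude: float = 7.0   # px, mounting vertical oscillation
    n_distractors: int = 1
    occluders: tuple[tuple[int, int, int, int], ...] = ()  # (top, left, h, w)
    blur_sigma: float = 0.0
    illumination: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.behavior not in BEHAVIORS:
            raise InvalidSpecError(f"unknown behavior {self.behavior!r}")
        if self.t_frames < 2:
            raise InvalidSpecError("clips need at least 2 frames")
        axes = self.body_axes or _BODY_AXES[self.behavior]
        object.__setattr__(self, "body_axes", tuple(float(a) for a in axes))
        h, w = self.canvas
        if 2 * max(self.body_axes) >= min(h, w):
            raise InvalidSpecError(
                f"body (half-axes {self.body_axes}) does not fit the {self.canvas} canvas"
            )
        if self.behavior == "walking" and self.velocity < 2 * self.jitter:
            raise InvalidSpecError(
                f"walking velocity {self.velocity} must be >= 2x jitter {self.jitter} "
                "to keep the temporal cue separable"
            )
        if self.behavior in ("standing", "lying"):
            stand = _BODY_AXES["standing"][0] / _BODY_AXES["standing"][1]
            lie = _BODY_AXES["lying"][0] / _BODY_AXES["lying"][1]
            if stand / lie < 1.5:
                raise InvalidSpecError("standing/lying aspect ratios too similar")


@dataclass
class ClipRecord:
    """Rendered clip: 8-bit frames, label, provenance spec, foreground masks."""

    frames: np.ndarray            # (T, H, W, 3) uint8
    label: str
    spec: SceneSpec
    masks: np.ndarray             # (T, H, W) bool
    centroids: np.ndarray         # (T, 2) float, foreground centroid (row, col)
    overlap: np.ndarray | None = None  # (T,) bool, two-body pixel overlap (mounting)

    def __post_init__(self):
        if self.frames.dtype != np.uint8:
            raise ValueError("frames must be 8-bit")
        if self.masks.shape != self.frames.shape[:3]:
            raise ValueError("masks must align with frames")


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------


def _smooth_noise(rng, shape, scale=8, amp=1.0):
    coarse = rng.normal(0.0, 1.0, (shape[0] // scale + 2, shape[1] // scale + 2))
    sm = ndimage.zoom(coarse, (shape[0] / coarse.shape[0], shape[1] / coarse.shape[1]),
                      order=1)[: shape[0], : shape[1]]
    return amp * sm


def _ellipse(h, w, center, axes, angle):
    """Soft-edged ellipse coverage in [0,1] and its boolean mask."""
    yy, xx = np.mgrid[0:h, 0:w]
    cy, cx = center
    a, b = axes
    ca, sa = np.cos(angle), np.sin(angle)
    u = (xx - cx) * ca + (yy - cy) * sa
    v = -(xx - cx) * sa + (yy - cy) * ca
    r = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    cover = np.clip((1.0 - r) * max(a, b) * 0.8, 0.0, 1.0)
    return cover, r <= 1.0


def _body_positions(spec: SceneSpec, rng) -> tuple[np.ndarray, float]:
    """Per-frame centers (T,2) as (row, col) of the (first) body, plus heading."""
    h, w = spec.canvas
    t = spec.t_frames
    a = max(spec.body_axes)
    margin = a + 2.0
    if spec.behavior == "walking":
        theta = rng.uniform(0, 2 * np.pi)
        path = spec.velocity * (t - 1)
        d = np.array([np.sin(theta), np.cos(theta)])  # (drow, dcol)
        center = np.array([h / 2.0, w / 2.0]) + rng.uniform(-3, 3, 2)
        start = center - d * path / 2.0
        pos = np.empty((t, 2))
        p, v = start.copy(), d * spec.velocity
        lo = np.array([margin, margin])
        hi = np.array([h - 1 - margin, w - 1 - margin])
        for i in range(t):
            pos[i] = p
            p = p + v
            for ax in (0, 1):  # reflect at canvas margins
                if p[ax] < lo[ax]:
                    p[ax] = 2 * lo[ax] - p[ax]
                    v[ax] = -v[ax]
                elif p[ax] > hi[ax]:
                    p[ax] = 2 * hi[ax] - p[ax]
                    v[ax] = -v[ax]
        # perpendicular limb-phase wobble, small against the velocity
        perp = np.array([-d[1], d[0]])
        wobble = 0.5 * np.sin(np.arange(t) * 1.1 + rng.uniform(0, 2 * np.pi))
        pos = pos + perp[None, :] * wobble[:, None]
        return pos, theta
    anchor = np.array(
        [rng.uniform(margin + 4, h - 1 - margin - 4), rng.uniform(margin + 4, w - 1 - margin - 4)]
    )
    jit = rng.uniform(-spec.jitter, spec.jitter, (t, 2))
    angle = rng.uniform(0, np.pi) if spec.behavior != "standing" else rng.uniform(-0.3, 0.3)
    return anchor[None, :] + jit, angle


def generate_clip(spec: SceneSpec) -> ClipRecord:
    """Render one clip per the class kinematics; fully reproducible from the seed."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.canvas
    t = spec.t_frames

    background = np.clip(
        _BACKGROUND_BASE + _smooth_noise(rng, (h, w), scale=8, amp=18.0)
        + rng.normal(0, 4, (h, w)),
        0,
        255,
    )
    # static distractor bodies, dimmer than the oracle threshold
    for _ in range(spec.n_distractors):
        c = (rng.uniform(6, h - 6), rng.uniform(6, w - 6))
        cover, _ = _ellipse(h, w, c, (7.0, 4.0), rng.uniform(0, np.pi))
        background = background * (1 - cover) + cover * (
            _DISTRACTOR_INTENSITY + rng.normal(0, 3)
        )

    body_tex = _smooth_noise(rng, (h, w), scale=4, amp=12.0)
    positions, heading = _body_positions(spec, rng)

    frames = np.empty((t, h, w, 3), dtype=np.uint8)
    masks = np.zeros((t, h, w), dtype=bool)
    centroids = np.zeros((t, 2))
    overlap = np.zeros(t, dtype=bool) if spec.behavior == "mounting" else None

    if spec.behavior == "mounting":
        base_center = np.array([h * 0.62, w * 0.5]) + rng.uniform(-3, 3, 2)
        axes2 = (spec.body_axes[0] * 0.9, spec.body_axes[1] * 0.9)
        phase = rng.uniform(0, 2 * np.pi)
        period = max(6.0, t / 2.0)
        gap = spec.body_axes[1] + axes2[0] * 0.35  # separation amplitude anchor

    channel_gain = np.array([1.0, 0.93, 0.82])  # grayish-brown tint
    for i in range(t):
        canvas = background.copy()
        if spec.behavior == "mounting":
            cover1, m1 = _ellipse(h, w, tuple(base_center), spec.body_axes, 0.15)
            offset = gap * (0.55 + 0.75 * np.sin(2 * np.pi * i / period + phase))
            c2 = (base_center[0] - spec.body_axes[1] - offset, base_center[1])
            cover2, m2 = _ellipse(h, w, c2, axes2, np.pi / 2 + 0.1)
            canvas = canvas * (1 - cover1) + cover1 * (_BODY_INTENSITY + body_tex)
            canvas = canvas * (1 - cover2) + cover2 * (_SECOND_BODY_INTENSITY + body_tex)
            mask = m1 | m2
            overlap[i] = bool((m1 & m2).any())
        else:
            angle = heading if spec.behavior == "walking" else heading
            cover, mask = _ellipse(h, w, tuple(positions[i]), spec.body_axes, angle)
            canvas = canvas * (1 - cover) + cover * (_BODY_INTENSITY + body_tex)
        masks[i] = mask
        ys, xs = np.nonzero(mask)
        centroids[i] = (ys.mean(), xs.mean()) if ys.size else (np.nan, np.nan)
        frames[i] = np.clip(canvas[..., None] * channel_gain[None, None, :], 0, 255).astype(
            np.uint8
        )

    record = ClipRecord(frames=frames, label=spec.behavior, spec=spec,
                        masks=masks, centroids=centroids, overlap=overlap)
    if spec.illumination != 1.0 or spec.blur_sigma > 0 or spec.occluders:
        record = apply_degradations(record, spec)
    return record


def apply_degradations(clip: ClipRecord, spec: SceneSpec) -> ClipRecord:
    """Illumination gain, then Gaussian blur, then occluder rectangles.

    The label is unchanged; foreground masks are clipped by occluders.
    """
    frames = clip.frames.astype(np.float64)
    masks = clip.masks.copy()
    if spec.illumination != 1.0:
        frames = frames * spec.illumination
    if spec.blur_sigma > 0:
        frames = np.stack(
            [ndimage.gaussian_filter(f, (spec.blur_sigma, spec.blur_sigma, 0))
             for f in frames]
        )
    for top, left, hh, ww in spec.occluders:
        frames[:, top : top + hh, left : left + ww, :] = 78.0
        masks[:, top : top + hh, left : left + ww] = False
    return ClipRecord(
        frames=np.clip(frames, 0, 255).astype(np.uint8),
        label=clip.label,
        spec=spec,
        masks=masks,
        centroids=clip.centroids,
        overlap=clip.overlap,
    )


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------


def _ratio_counts(total: int) -> dict[str, int]:
    """Scale the reference per-class counts to ``total`` (largest-remainder)."""
    weights = np.array([TABLE_COUNTS[b] for b in BEHAVIORS], dtype=np.float64)
    exact = weights / weights.sum() * total
    counts = np.floor(exact).astype(int)
    order = np.argsort(-(exact - counts))
    for k in range(total - counts.sum()):
        counts[order[k % 4]] += 1
    return {b: max(1, int(c)) for b, c in zip(BEHAVIORS, counts)}


def generate_dataset(
    n_per_class: dict[str, int] | tuple[int, int, int, int] | None = None,
    total: int | None = None,
    seed: int = 0,
    canvas: tuple[int, int] = (64, 64),
    fps: float = 12.5,
    degradation: str = "none",
) -> list[ClipRecord]:
    """Generate a labeled clip collection.

    Either ``n_per_class`` gives exact per-class counts, or ``total`` is
    split according to the reference dataset's class ratios.  Clip durations
    are drawn uniformly from each class's duration range.  ``degradation``
    is ``none`` (clean), ``mild`` (light blur/illumination) or ``heavy``.
    Identical arguments and seed reproduce the dataset byte for byte.
    """
    if (n_per_class is None) == (total is None):
        raise ValueError("give exactly one of n_per_class or total")
    if n_per_class is None:
        counts = _ratio_counts(int(total))
    elif isinstance(n_per_class, dict):
        counts = {b: int(n_per_class[b]) for b in BEHAVIORS}
    else:
        counts = dict(zip(BEHAVIORS, (int(c) for c in n_per_class)))
    if any(c < 1 for c in counts.values()):
        raise ValueError(f"per-class counts must be >= 1, got {counts}")
    if degradation not in ("none", "mild", "heavy"):
        raise ValueError(f"unknown degradation level {degradation!r}")

    rng = np.random.default_rng(seed)
    records: list[ClipRecord] = []
    for behavior in BEHAVIORS:
        lo, hi = DURATION_RANGES[behavior]
        for _ in range(counts[behavior]):
            duration = rng.uniform(lo, hi)
            t_frames = max(4, int(round(duration * fps)))
            clip_seed = int(rng.integers(0, 2**31 - 1))
            extras: dict = {}
            if degradation != "none":
                heavy = degradation == "heavy"
                extras["illumination"] = float(
                    rng.uniform(0.35 if heavy else 0.7, 1.1)
                )
                extras["blur_sigma"] = float(rng.uniform(1.5, 3.0) if heavy
                                             else rng.uniform(0.0, 0.8))
                if rng.random() < (0.8 if heavy else 0.3):
                    oh = int(rng.integers(8, 20))
                    ow = int(rng.integers(8, 20))
                    extras["occluders"] = (
                        (int(rng.integers(0, canvas[0] - oh)),
                         int(rng.integers(0, canvas[1] - ow)), oh, ow),
                    )
            spec = SceneSpec(
                behavior=behavior,
                canvas=canvas,
                t_frames=t_frames,
                fps=fps,
                seed=clip_seed,
                **extras,
            )
            records.append(generate_clip(spec))
    return records


def dataset_checksum(records: list[ClipRecord]) -> str:
    """SHA-256 over frames, labels and masks — the determinism fingerprint."""
    digest = hashlib.sha256()
    for rec in records:
        digest.update(rec.label.encode())
        digest.update(rec.frames.tobytes())
        digest.update(rec.masks.tobytes())
    return digest.hexdigest()


# ---------------------------------------------------------------------------
# kinematic oracle
# ---------------------------------------------------------------------------

_MIN_COMPONENT_AREA = 40


def _frame_components(gray: np.ndarray) -> list[tuple[float, np.ndarray, float]]:
    """Large bright components of one frame: (area, centroid, aspect)."""
    bw = gray > _FOREGROUND_THRESHOLD
    labels, n = ndimage.label(bw)
    comps = []
    for idx in range(1, n + 1):
        ys, xs = np.nonzero(labels == idx)
        if ys.size < _MIN_COMPONENT_AREA:
            continue
        centroid = np.array([ys.mean(), xs.mean()])
        cov = np.cov(np.stack([ys, xs]).astype(np.float64))
        eig = np.sort(np.linalg.eigvalsh(cov))
        aspect = float(np.sqrt(max(eig[1], 1e-9) / max(eig[0], 1e-9)))
        comps.append((float(ys.size), centroid, aspect))
    comps.sort(key=lambda c: -c[0])
    return comps


_WALK_STEP_THRESHOLD = 1.5   # px/frame; walking moves >= 2, jitter stays well below
_ASPECT_THRESHOLD = 1.7      # between standing (~2.4) and lying (~1.2) blob aspects
_TWO_BODY_FRACTION = 0.12    # fraction of frames showing two separated bodies


def oracle_classify(clip: ClipRecord) -> str:
    """Rule-based label from component count, centroid motion and blob aspect.

    Two separated bright components in enough frames -> mounting; sustained
    centroid motion -> walking; otherwise the blob aspect ratio decides
    standing (elongated) vs lying (round).  Always returns a label.
    """
    gray = clip.frames.astype(np.float64).mean(axis=-1)
    gain = clip.spec.illumination if clip.spec.illumination > 0 else 1.0
    if gain != 1.0:
        gray = gray / gain  # undo global illumination for thresholding
    per_frame = [_frame_components(g) for g in gray]
    n_frames = len(per_frame)
    two_body = sum(1 for comps in per_frame if len(comps) >= 2) / n_frames
    if two_body >= _TWO_BODY_FRACTION:
        return "mounting"
    centroids = np.array(
        [comps[0][1] if comps else (np.nan, np.nan) for comps in per_frame]
    )
    valid = ~np.isnan(centroids[:, 0])
    if valid.sum() >= 2:
        pts = centroids[valid]
        steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.median(steps) >= _WALK_STEP_THRESHOLD:
            return "walking"
    aspects = [comps[0][2] for comps in per_frame if comps]
    aspect = float(np.median(aspects)) if aspects else 1.0
    return "standing" if aspect >= _ASPECT_THRESHOLD else "lying"


def oracle_classify_frame(frame: np.ndarray) -> str:
    """Spatial-only oracle on a single frame: no temporal cue is available.

    It can tell standing from lying (shape) and spot mounting (two bodies in
    one frame), but it cannot assert walking — a walking body is spatially
    identical to a standing one — so it never returns ``walking``.
    """
    gray = np.asarray(frame, dtype=np.float64).mean(axis=-1)
    comps = _frame_components(gray)
    if len(comps) >= 2:
        return "mounting"
    aspect = comps[0][2] if comps else 1.0
    return "standing" if aspect >= _ASPECT_THRESHOLD else "lying"
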