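"""Synthetic clip generator: kinematics, degradations, determinism, oracle validity."""

import numpy as np
import pytest
from scipy import ndimage

from x3dfast.exceptions import InvalidSpecError
from x3dfast.synthetic_videos import (
    BEHAVIORS,
    TABLE_COUNTS,
    SceneSpec,
    apply_degradations,
    dataset_checksum,
    generate_clip,
    generate_dataset,
    oracle_classify,
    oracle_classify_frame,
)
from x3dfast.synthetic_videos import _ratio_counts


class TestKinematics:
    def test_walking_net_displacement_matches_velocity(self):
        for seed in range(5):
            clip = generate_clip(SceneSpec(behavior="walking", t_frames=16,
                                           velocity=2.0, seed=seed))
            disp = np.linalg.norm(clip.centroids[-1] - clip.centroids[0])
            assert disp == pytest.approx(30.0, abs=2.0)  # (T-1) * v

    def test_standing_jitter_bounded(self):
        clip = generate_clip(SceneSpec(behavior="standing", t_frames=20,
                                       jitter=1.0, seed=4))
        center = clip.centroids.mean(axis=0)
        assert np.linalg.norm(clip.centroids - center, axis=1).max() <= 2.0

    def test_mounting_overlap_at_least_half_the_frames(self):
        for seed in range(5):
            clip = generate_clip(SceneSpec(behavior="mounting", t_frames=30, seed=seed))
            assert clip.overlap.sum() >= clip.spec.t_frames / 2

    def test_standing_and_lying_aspects_differ(self):
        stand = generate_clip(SceneSpec(behavior="standing", seed=1))
        lie = generate_clip(SceneSpec(behavior="lying", seed=1))
        a_s = stand.spec.body_axes[0] / stand.spec.body_axes[1]
        a_l = lie.spec.body_axes[0] / lie.spec.body_axes[1]
        assert a_s / a_l >= 1.5

    def test_oversized_body_rejected(self):
        with pytest.raises(InvalidSpecError, match="canvas"):
            SceneSpec(behavior="standing", canvas=(32, 32), body_axes=(20.0, 8.0))

    def test_slow_walk_violating_separability_rejected(self):
        with pytest.raises(InvalidSpecError, match="jitter"):
            SceneSpec(behavior="walking", velocity=1.0, jitter=1.0)


class TestDegradations:
    def test_identity_when_no_degradation_requested(self):
        clip = generate_clip(SceneSpec(behavior="lying", seed=2))
        out = apply_degradations(clip, clip.spec)
        assert np.array_equal(out.frames, clip.frames)
        assert np.array_equal(out.masks, clip.masks)

    def test_illumination_gain_scales_mean_intensity(self):
        clip = generate_clip(SceneSpec(behavior="standing", seed=3))
        dark_spec = SceneSpec(behavior="standing", seed=3, illumination=0.4)
        dark = apply_degradations(clip, dark_spec)
        ratio = dark.frames.mean() / clip.frames.mean()
        assert ratio == pytest.approx(0.4, abs=0.02)

    def test_occluder_clips_foreground_mask_geometrically(self):
        clip = generate_clip(SceneSpec(behavior="lying", seed=5))
        cy, cx = clip.centroids[0].astype(int)
        occ = (cy - 6, cx - 6, 12, 12)
        spec = SceneSpec(behavior="lying", seed=5, occluders=(occ,))
        out = apply_degradations(clip, spec)
        lost = clip.masks[0].sum() - out.masks[0].sum()
        expected = (clip.masks[0][occ[0] : occ[0] + 12, occ[1] : occ[1] + 12]).sum()
        assert lost == expected > 0

    def test_blur_softens_edges_without_touching_masks(self):
        clip = generate_clip(SceneSpec(behavior="standing", seed=6))
        spec = SceneSpec(behavior="standing", seed=6, blur_sigma=2.0)
        out = apply_degradations(clip, spec)
        grad_sharp = np.abs(np.diff(clip.frames[0].astype(float), axis=1)).mean()
        grad_blur = np.abs(np.diff(out.frames[0].astype(float), axis=1)).mean()
        assert grad_blur < grad_sharp
        assert np.array_equal(out.masks, clip.masks)


class TestDatasetGeneration:
    def test_exact_per_class_counts(self):
        records = generate_dataset(n_per_class=(3, 4, 5, 6), seed=0)
        counts = {b: sum(r.label == b for r in records) for b in BEHAVIORS}
        assert counts == {"standing": 3, "lying": 4, "walking": 5, "mounting": 6}

    def test_ratio_mode_tracks_reference_proportions(self):
        counts = _ratio_counts(1000)
        total_ref = sum(TABLE_COUNTS.values())
        for b in BEHAVIORS:
            assert counts[b] == pytest.approx(1000 * TABLE_COUNTS[b] / total_ref, abs=1)
        assert sum(counts.values()) == 1000

    def test_mounting_clips_longest(self):
        records = generate_dataset(n_per_class=(5, 5, 5, 5), seed=3)
        mean_t = {b: np.mean([r.spec.t_frames for r in records if r.label == b])
                  for b in BEHAVIORS}
        assert mean_t["mounting"] > max(mean_t["standing"], mean_t["lying"])

    def test_byte_reproducibility_from_seed(self):
        a = generate_dataset(n_per_class=(3, 3, 3, 3), seed=9)
        b = generate_dataset(n_per_class=(3, 3, 3, 3), seed=9)
        c = generate_dataset(n_per_class=(3, 3, 3, 3), seed=10)
        assert dataset_checksum(a) == dataset_checksum(b)
        assert dataset_checksum(a) != dataset_checksum(c)


class TestOracle:
    def test_clean_clips_classified_reliably(self):
        records = generate_dataset(n_per_class=(20, 20, 20, 20), seed=21)
        acc = np.mean([oracle_classify(r) == r.label for r in records])
        assert acc >= 0.95

    def test_heavy_degradation_stays_above_chance(self):
        records = generate_dataset(n_per_class=(15, 15, 15, 15), seed=22,
                                   degradation="heavy")
        acc = np.mean([oracle_classify(r) == r.label for r in records])
        assert acc > 0.25

    def test_spatial_only_oracle_cannot_see_walking(self):
        """Single-frame shape cues separate standing/lying but not walking/standing."""
        records = generate_dataset(n_per_class=(25, 25, 25, 25), seed=23)
        static = [r for r in records if r.label in ("standing", "lying")]
        static_acc = np.mean(
            [oracle_classify_frame(r.frames[len(r.frames) // 2]) == r.label
             for r in static]
        )
        assert static_acc >= 0.9
        walkers = [r for r in records if r.label == "walking"]
        walk_calls = [oracle_classify_frame(r.frames[len(r.frames) // 2])
                      for r in walkers]
        # walking vs standing from one frame is chance-level: same body shape
        walk_vs_stand = np.mean([c == "walking" for c in walk_calls])
        assert walk_vs_stand <= 0.75
        assert np.mean([c == "standing" for c in walk_calls]) >= 0.8
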