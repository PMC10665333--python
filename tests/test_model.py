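"""Model assembly, loss/metric oracles, ablation accounting, CAM, checkpoints."""

import math

import numpy as np
import pytest

from x3dfast import nn
from x3dfast.exceptions import NotTrainedError
from x3dfast.model import (
    ModelConfig,
    X3DFast,
    compute_cam,
    cross_entropy,
    load_checkpoint,
    save_checkpoint,
    top1,
)


@pytest.fixture
def tiny_model():
    nn.set_seed(0)
    model = X3DFast(ModelConfig.tiny())
    model.eval()
    return model


def _clips(rng, n=2, hw=32):
    x3d = rng.normal(size=(n, 4, 3, hw, hw)).astype(np.float32)
    fast = rng.normal(size=(n, 8, 3, hw, hw)).astype(np.float32)
    return x3d, fast


class TestForward:
    def test_logits_shape_and_eval_determinism(self, tiny_model, rng):
        x3d, fast = _clips(rng)
        l1 = tiny_model.forward(x3d, fast).data
        l2 = tiny_model.forward(x3d, fast).data
        assert l1.shape == (2, 4)
        assert np.array_equal(l1, l2)

    def test_full_profile_forward_smoke(self, rng):
        nn.set_seed(0)
        model = X3DFast(ModelConfig.full())
        model.eval()
        assert model.x3d.num_groups() == 26
        x3d = rng.normal(size=(1, 8, 3, 64, 64)).astype(np.float32)
        fast = rng.normal(size=(1, 32, 3, 64, 64)).astype(np.float32)
        with nn.no_grad():
            logits = model.forward(x3d, fast)
        assert logits.shape == (1, 4)
        assert np.isfinite(logits.data).all()


class TestCrossEntropy:
    def test_perfect_prediction_zero_loss(self):
        y = np.eye(4)[[0, 1, 2, 3]]
        assert cross_entropy(y, y) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_prediction_log_m(self):
        p = np.full((5, 4), 0.25)
        y = np.eye(4)[[0, 1, 2, 3, 0]]
        assert cross_entropy(p, y) == pytest.approx(math.log(4), abs=1e-9)

    def test_hand_evaluated_two_sample_batch(self):
        p = np.array([[0.9, 0.05, 0.03, 0.02], [0.5, 0.2, 0.2, 0.1]])
        y = np.eye(4)[[0, 0]]
        expected = -(math.log(0.9) + math.log(0.5)) / 2  # = 0.3992538...
        assert cross_entropy(p, y) == pytest.approx(expected, abs=1e-9)

    def test_matches_bruteforce_oracle_on_random_batches(self, rng):
        for _ in range(100):
            n, m = int(rng.integers(1, 9)), int(rng.integers(2, 6))
            p = rng.dirichlet(np.ones(m), size=n)
            labels = rng.integers(0, m, size=n)
            y = np.eye(m)[labels]
            # independent oracle: explicit double loop over Eq. structure
            total = 0.0
            for i in range(n):
                for c in range(m):
                    if y[i, c] == 1.0:
                        total -= math.log(max(p[i, c], 1e-12))
            assert cross_entropy(p, y) == pytest.approx(total / n, abs=1e-6)

    def test_unnormalized_rows_rejected(self):
        p = np.array([[0.6, 0.6, 0.0, 0.0]])
        with pytest.raises(ValueError, match="sums to"):
            cross_entropy(p, np.eye(4)[[0]])


class TestTop1:
    def test_all_correct_and_three_quarters(self):
        scores = np.eye(4)
        assert top1(scores, np.arange(4)) == 1.0
        assert top1(scores, np.array([0, 1, 2, 0])) == 0.75

    def test_matches_counting_oracle_exactly(self, rng):
        scores = rng.normal(size=(1000, 4))
        labels = rng.integers(0, 4, size=1000)
        count = sum(1 for s, l in zip(scores, labels) if int(np.argmax(s)) == l)
        assert top1(scores, labels) == count / 1000

    def test_invariant_under_monotone_transformation(self, rng):
        scores = rng.normal(size=(50, 4))
        labels = rng.integers(0, 4, size=50)
        assert top1(scores, labels) == top1(np.exp(scores), labels) == top1(3 * scores - 7, labels)

    def test_tie_breaks_to_lowest_class_index(self):
        scores = np.array([[0.5, 0.5, 0.1, 0.1]])
        assert top1(scores, np.array([0])) == 1.0
        assert top1(scores, np.array([1])) == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            top1(np.empty((0, 4)), np.empty(0))


class TestAblationAccounting:
    """Each architecture switch changes exactly its own named parameters."""

    @staticmethod
    def _delta(cfg_a: ModelConfig, cfg_b: ModelConfig):
        nn.set_seed(0)
        a = dict(X3DFast(cfg_a).named_parameters())
        nn.set_seed(0)
        b = dict(X3DFast(cfg_b).named_parameters())
        only_a = {k for k in a if k not in b}
        only_b = {k for k in b if k not in a}
        diff = {k for k in a.keys() & b.keys() if a[k].shape != b[k].shape}
        total_delta = sum(p.data.size for p in a.values()) - sum(
            p.data.size for p in b.values()
        )
        part_delta = (
            sum(a[k].data.size for k in only_a)
            - sum(b[k].data.size for k in only_b)
            + sum(a[k].data.size - b[k].data.size for k in diff)
        )
        return only_a, only_b, diff, total_delta, part_delta

    def test_action_switch_removes_only_attention_gates(self):
        only_a, only_b, diff, total, parts = self._delta(
            ModelConfig.tiny(), ModelConfig.tiny(use_action=False)
        )
        assert not only_b and not diff
        assert only_a and all(".attention." in k for k in only_a)
        assert total == parts > 0

    def test_r2plus1d_switch_swaps_only_fast_cores(self):
        only_a, only_b, diff, total, parts = self._delta(
            ModelConfig.tiny(), ModelConfig.tiny(use_r2plus1d=False)
        )
        assert not diff
        changed = only_a | only_b
        assert changed and all(k.startswith("fast.stages.") for k in changed)
        assert total == parts

    def test_lateral_switch_accounting_names_every_changed_part(self):
        only_a, only_b, diff, total, parts = self._delta(
            ModelConfig.tiny(), ModelConfig.tiny(use_lateral=False)
        )
        assert not only_b
        assert only_a and all(k.startswith("laterals.") for k in only_a)
        # concatenation feeds stages 2-4 and the predictor: their input widths change
        for k in diff:
            assert k == "fc1.weight" or (
                k.startswith("x3d.stages.") and ".blocks.0." in k
            ), k
        assert total == parts > 0

    def test_switches_toggle_independently(self):
        seen = set()
        for lat in (True, False):
            for r2 in (True, False):
                for act in (True, False):
                    cfg = ModelConfig.tiny(use_lateral=lat, use_r2plus1d=r2,
                                           use_action=act)
                    nn.set_seed(0)
                    seen.add(X3DFast(cfg).num_parameters())
        assert len(seen) == 8  # every arm has a distinct parameter count


class TestCam:
    def test_untrained_model_rejected(self, tiny_model, rng):
        x3d, fast = _clips(rng, n=1)
        with pytest.raises(NotTrainedError):
            compute_cam(tiny_model, x3d[0], fast[0])

    def test_heatmap_shape_nonnegative_and_normalized(self, tiny_model, rng):
        tiny_model.trained = True
        x3d, fast = _clips(rng, n=1)
        cam = compute_cam(tiny_model, x3d[0], fast[0], target_class=1)
        t, h, w = cam.heatmaps.shape
        assert t == 4 and h == w == 2  # final fused feature volume at 32 px input
        assert (cam.heatmaps >= 0).all()
        for frame in cam.heatmaps:
            assert frame.max() == pytest.approx(1.0) or frame.max() == 0.0

    def test_zero_clip_gives_zero_heatmap(self, tiny_model):
        tiny_model.trained = True
        x3d = np.zeros((4, 3, 32, 32), dtype=np.float32)
        fast = np.zeros((8, 3, 32, 32), dtype=np.float32)
        cam = compute_cam(tiny_model, x3d, fast, target_class=0)
        assert np.all(cam.heatmaps == 0.0)

    def test_upsampling_preserves_peak_cell(self, tiny_model, rng):
        tiny_model.trained = True
        x3d, fast = _clips(rng, n=1)
        coarse = compute_cam(tiny_model, x3d[0], fast[0], target_class=2)
        fine = compute_cam(tiny_model, x3d[0], fast[0], target_class=2,
                           upsample_to=(32, 32))
        assert fine.heatmaps.shape == (4, 32, 32)
        k = 0
        cy, cx = np.unravel_index(np.argmax(coarse.heatmaps[k]), (2, 2))
        py, px = np.unravel_index(np.argmax(fine.heatmaps[k]), (32, 32))
        assert abs(py - (cy * 16 + 8)) <= 8 and abs(px - (cx * 16 + 8)) <= 8


class TestCheckpoint:
    def test_round_trip_reproduces_logits(self, tiny_model, rng, tmp_path):
        tiny_model.trained = True
        x3d, fast = _clips(rng)
        before = tiny_model.forward(x3d, fast).data
        path = tmp_path / "model.npz"
        save_checkpoint(path, tiny_model, seed=7, history=[{"epoch": 0}])
        restored, meta = load_checkpoint(path)
        after = restored.forward(x3d, fast).data
        assert np.array_equal(before, after)
        assert meta["seed"] == 7 and meta["history"] == [{"epoch": 0}]
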