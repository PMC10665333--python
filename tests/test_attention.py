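"""Excitation-branch contracts: mask shapes and ranges, residual bounds, motion rules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from x3dfast.action_attention import (
    ActionModule,
    CEBranch,
    ExcitationBranchConfig,
    MEBranch,
    STEBranch,
)
from x3dfast.exceptions import InvalidSpecError, MotionUndefinedError
from x3dfast.nn import Tensor

CFG = ExcitationBranchConfig()


def _zero_params(module):
    for p in module.parameters():
        p.data[:] = 0.0


class TestMaskContracts:
    def test_ste_mask_shape_and_range(self, rng):
        branch = STEBranch(16, CFG)
        x = Tensor(rng.normal(size=(2, 8, 16, 32, 32)).astype(np.float32))
        mask = branch.mask(x).data
        assert mask.shape == (2, 8, 1, 32, 32)
        assert (mask > 0).all() and (mask < 1).all()
        assert branch(x).shape == (2, 8, 16, 32, 32)

    def test_ce_mask_shape_and_squeeze_width(self, rng):
        branch = CEBranch(32, CFG)
        assert branch.squeeze.c_out == math.ceil(32 / 16) == 2
        x = Tensor(rng.normal(size=(2, 4, 32, 5, 5)).astype(np.float32))
        mask = branch.mask(x).data
        assert mask.shape == (2, 4, 32, 1, 1)
        assert (mask > 0).all() and (mask < 1).all()

    def test_me_motion_volume_and_mask_shapes(self, rng):
        branch = MEBranch(32, CFG)
        x = Tensor(rng.normal(size=(2, 6, 32, 7, 7)).astype(np.float32))
        fm = branch.motion_volume(x).data
        assert fm.shape == (2, 6, 2, 7, 7)  # C/r with r=16
        assert branch.mask(x).data.shape == (2, 6, 32, 1, 1)

    @given(st.integers(2, 5), st.integers(1, 24), st.integers(3, 8))
    @settings(max_examples=12, deadline=None, derandomize=True, database=None)
    def test_masks_stay_in_open_unit_interval(self, t, c, hw):
        from x3dfast import nn as x3d_nn

        x3d_nn.set_seed(t * 31 + c)  # branch init independent of example order
        rng = np.random.default_rng(t * 100 + c)
        # float64: the open-interval property is exact in real arithmetic at
        # moderate scale, while a saturated float32 sigmoid rounds to 1.0
        x = Tensor(2 * rng.normal(size=(1, t, c, hw, hw)))
        for branch in (STEBranch(c, CFG), CEBranch(c, CFG), MEBranch(c, CFG)):
            mask = branch.mask(x).data
            assert (mask > 0).all() and (mask < 1).all()


class TestResidualForm:
    def test_positive_input_bounded_between_x_and_2x(self, rng):
        x_data = rng.uniform(0.1, 2.0, size=(1, 4, 8, 6, 6))  # float64 keeps masks < 1
        x = Tensor(x_data)
        for branch in (STEBranch(8, CFG), CEBranch(8, CFG), MEBranch(8, CFG)):
            y = branch(x).data
            assert (y > x_data).all() and (y < 2 * x_data).all()

    def test_zero_input_is_fixed_point_with_zero_bias(self):
        x = Tensor(np.zeros((1, 4, 8, 5, 5), dtype=np.float32))
        for branch in (STEBranch(8, CFG), CEBranch(8, CFG), MEBranch(8, CFG)):
            _zero_params(branch)
            assert np.all(branch(x).data == 0.0)

    def test_zeroed_ste_scorer_yields_half_mask(self):
        branch = STEBranch(8, CFG)
        _zero_params(branch)
        x = Tensor(np.zeros((1, 3, 8, 4, 4), dtype=np.float32))
        assert np.all(branch.mask(x).data == 0.5)


class TestMotionRules:
    def test_temporally_constant_input_differences_identical(self, rng):
        branch = MEBranch(8, CFG)
        frame = rng.normal(size=(1, 1, 8, 6, 6)).astype(np.float32)
        x = Tensor(np.repeat(frame, 5, axis=1))
        fm = branch.motion_volume(x).data
        # every pre-pad slice equal; final slot zero-padded
        for t in range(1, 4):
            assert np.allclose(fm[:, t], fm[:, 0], atol=1e-6)
        assert np.all(fm[:, 4] == 0.0)

    def test_single_frame_input_rejected_with_bypass_hint(self, rng):
        branch = MEBranch(8, CFG)
        x = Tensor(rng.normal(size=(1, 1, 8, 6, 6)).astype(np.float32))
        with pytest.raises(MotionUndefinedError, match="bypass"):
            branch(x)


class TestActionModule:
    def test_output_is_average_of_independent_branches(self, rng):
        module = ActionModule(8, CFG)
        x = Tensor(rng.normal(size=(2, 4, 8, 6, 6)).astype(np.float32))
        expected = (module.ste(x).data + module.ce(x).data + module.me(x).data) / 3.0
        assert np.allclose(module(x).data, expected, atol=1e-6)

    def test_shape_preserved_and_deterministic(self, rng):
        module = ActionModule(16, CFG)
        module.eval()
        x = Tensor(rng.normal(size=(2, 8, 16, 8, 8)).astype(np.float32))
        y1 = module(x).data
        y2 = module(Tensor(x.data.copy())).data
        assert y1.shape == (2, 8, 16, 8, 8)
        assert np.array_equal(y1, y2)

    def test_sum_combination_configurable(self, rng):
        module = ActionModule(4, ExcitationBranchConfig(combine="sum"))
        x = Tensor(rng.normal(size=(1, 3, 4, 4, 4)).astype(np.float32))
        expected = module.ste(x).data + module.ce(x).data + module.me(x).data
        assert np.allclose(module(x).data, expected, atol=1e-6)

    def test_even_kernel_rejected(self):
        with pytest.raises(InvalidSpecError):
            ExcitationBranchConfig(ste_kernel=4)
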