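"""Interpolation network: DACB masks, backward warping, flow estimation,
and full synthesis."""

import numpy as np
import pytest

from angiosynth.nn.autodiff import Tensor
from angiosynth.nn.checkpoint import load_checkpoint, save_checkpoint
from angiosynth.nn.layers import (
    DirectionAwareBlock,
    apply_dacb,
    orientation_mask,
)
from angiosynth.nn.model import (
    FlowField,
    FrameSynthesisModel,
    ModelConfig,
    SynthesisRequest,
    backward_warp,
    synthesize_intermediate,
)


class TestOrientationMasks:
    def test_canonical_masks(self):
        np.testing.assert_array_equal(
            orientation_mask(0.0), [[0, 0, 0], [1, 1, 1], [0, 0, 0]]
        )
        np.testing.assert_array_equal(
            orientation_mask(90.0), [[0, 1, 0], [0, 1, 0], [0, 1, 0]]
        )
        np.testing.assert_array_equal(
            orientation_mask(45.0), [[0, 0, 1], [0, 1, 0], [1, 0, 0]]
        )
        np.testing.assert_array_equal(
            orientation_mask(135.0), [[1, 0, 0], [0, 1, 0], [0, 0, 1]]
        )


class TestDACB:
    def test_output_spatial_shape(self):
        x = np.random.default_rng(0).normal(size=(6, 17, 23)).astype(np.float32)
        out = apply_dacb(x, seed=1)
        assert out.shape[1:] == (17, 23)

    def test_requires_orientation(self):
        with pytest.raises(ValueError):
            DirectionAwareBlock(4, 4, orientations=())

    def test_masked_positions_blind(self):
        # input nonzero only off the 0-degree line: the 0-degree branch sees
        # nothing but its bias
        block = DirectionAwareBlock(1, 4, orientations=(0.0,), rng=np.random.default_rng(2))
        x = np.zeros((1, 1, 9, 9), dtype=np.float32)
        x[0, 0, ::2, :] = 0.0
        # energise rows 0 and 2 around the centre row of each 3x3 window:
        # a checkerboard of rows that never touches the kernel's centre row
        # is impossible globally, so instead probe single pixels
        branch = block.branches[0]
        for r, c in [(4, 4), (2, 7)]:
            probe = np.zeros((1, 1, 9, 9), dtype=np.float32)
            probe[0, 0, r - 1, c] = 5.0  # directly above: off the 0-degree line
            out = branch(Tensor(probe)).data
            bias_only = branch(Tensor(np.zeros_like(probe))).data
            np.testing.assert_allclose(out[0, :, r, c], bias_only[0, :, r, c], atol=1e-6)

    def test_horizontal_stimulus_prefers_horizontal_branch(self):
        block = DirectionAwareBlock(
            1, 4, orientations=(0.0, 90.0), rng=np.random.default_rng(3), init="average"
        )
        # signed stimulus in the normalized convention: a bright line on a
        # dark background; the aligned branch preserves it, the orthogonal
        # branch averages it away
        x = np.full((1, 1, 16, 16), -1.0, dtype=np.float32)
        x[0, 0, 8, 2:14] = 1.0  # horizontal line
        outs = block.branch_outputs(Tensor(x))
        act = [float(np.abs(o.data).mean()) for o in outs]
        assert act[0] > act[1]


class TestBackwardWarp:
    def test_zero_flow_identity(self):
        src = np.random.default_rng(1).normal(size=(7, 9))
        out = backward_warp(src, np.zeros((7, 9, 2)))
        np.testing.assert_array_equal(out, src)

    def test_integer_shift_matches_index_oracle(self):
        rng = np.random.default_rng(2)
        src = rng.normal(size=(6, 8))
        flow = np.zeros((6, 8, 2))
        flow[..., 0] = 1.0  # sample one column to the right
        out = backward_warp(src, flow)
        oracle = np.empty_like(src)
        oracle[:, :-1] = src[:, 1:]
        oracle[:, -1] = src[:, -1]  # border duplication
        np.testing.assert_allclose(out, oracle, atol=1e-6)

    def test_half_pixel_on_linear_ramp_exact(self):
        xx = np.tile(np.arange(8.0), (8, 1))
        flow = np.zeros((8, 8, 2))
        flow[..., 0] = 0.5
        out = backward_warp(xx, flow)
        np.testing.assert_allclose(out[:, :7], xx[:, :7] + 0.5, atol=1e-6)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            backward_warp(np.zeros((4, 4)), np.zeros((5, 4, 2)))

    def test_against_bruteforce_bilinear_oracle(self):
        # independent per-pixel implementation of clamped bilinear sampling
        rng = np.random.default_rng(3)
        for _ in range(100):
            src = rng.normal(size=(8, 8))
            flow = rng.uniform(-3, 3, size=(8, 8, 2))
            out = backward_warp(src, flow)
            expect = np.empty_like(src)
            for r in range(8):
                for c in range(8):
                    gx = min(max(c + flow[r, c, 0], 0.0), 7.0)
                    gy = min(max(r + flow[r, c, 1], 0.0), 7.0)
                    x0, y0 = int(min(np.floor(gx), 6)), int(min(np.floor(gy), 6))
                    fx, fy = gx - x0, gy - y0
                    expect[r, c] = (
                        src[y0, x0] * (1 - fx) * (1 - fy)
                        + src[y0, x0 + 1] * fx * (1 - fy)
                        + src[y0 + 1, x0] * (1 - fx) * fy
                        + src[y0 + 1, x0 + 1] * fx * fy
                    )
            assert np.abs(out - expect).max() < 1e-5


class TestModelConfig:
    def test_channel_doubling(self):
        cfg = ModelConfig(base_channels=16, n_scales=4)
        assert [cfg.channels_at(s) for s in range(4)] == [16, 32, 64, 128]

    def test_rejects_single_scale(self):
        with pytest.raises(ValueError):
            ModelConfig(n_scales=1)

    def test_roundtrip_dict(self):
        cfg = ModelConfig(base_channels=8, n_scales=2, use_attention=False)
        assert ModelConfig.from_dict(cfg.to_dict()) == cfg


class TestFlowEstimation:
    def test_output_shapes_and_finiteness(self):
        model = FrameSynthesisModel(ModelConfig(base_channels=4, n_scales=2, seed=0,
                                                use_attention=False))
        rng = np.random.default_rng(4)
        f0 = rng.uniform(-1, 1, size=(16, 16))
        f1 = rng.uniform(-1, 1, size=(16, 16))
        fl0, fl1 = model.estimate_bidirectional_flow(f0, f1, t=0.0)
        assert fl0.flow.shape == (16, 16, 2)
        assert fl1.flow.shape == (16, 16, 2)

    def test_translation_model_midpoint_displacement(self, translation_model):
        # trained on 3 px shifts: the midpoint flow magnitude should be about
        # half the shift
        model, seqs = translation_model
        mags = []
        for s in seqs[:8]:
            fl0, fl1 = model.estimate_bidirectional_flow(s[0], s[2], t=0.0)
            mags.append(0.5 * (fl0.magnitude.mean() + fl1.magnitude.mean()))
        assert 1.0 <= float(np.mean(mags)) <= 2.0

    def test_static_model_near_zero_flow(self, static_model):
        rng = np.random.default_rng(5)
        from scipy import ndimage as _ndi

        base = _ndi.gaussian_filter(rng.normal(0, 1, size=(32, 32)), 2.5)
        base = 2.0 * (base - base.min()) / (base.max() - base.min()) - 1.0
        fl0, fl1 = static_model.estimate_bidirectional_flow(base, base, t=0.0)
        assert fl0.magnitude.mean() < 0.5
        assert fl1.magnitude.mean() < 0.5

    def test_flowfield_validates(self):
        with pytest.raises(ValueError):
            FlowField(np.full((4, 4, 2), np.nan))
        with pytest.raises(ValueError):
            FlowField(np.zeros((4, 4, 3)))


class TestSynthesis:
    @pytest.fixture(scope="class")
    def small_model(self):
        return FrameSynthesisModel(ModelConfig(base_channels=4, n_scales=2, seed=0))

    def test_shape_and_bounds(self, small_model):
        rng = np.random.default_rng(6)
        f0 = rng.uniform(-1, 1, size=(16, 16))
        f1 = rng.uniform(-1, 1, size=(16, 16))
        out = synthesize_intermediate(SynthesisRequest(f0, f1, 0.25), small_model)
        assert out.shape == (16, 16)
        assert out.min() >= -1.0 and out.max() <= 1.0

    def test_endpoint_timesteps_rejected(self):
        f = np.zeros((16, 16))
        for t in (-1.0, 1.0, 1.5):
            with pytest.raises(ValueError):
                SynthesisRequest(f, f, t)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            SynthesisRequest(np.zeros((16, 16)), np.zeros((16, 32)), 0.0)

    def test_indivisible_size_rejected(self, small_model):
        f = np.zeros((15, 15))
        with pytest.raises(ValueError):
            small_model.synthesize(f, f, 0.0)

    def test_forward_deterministic(self, small_model):
        rng = np.random.default_rng(7)
        f0 = rng.uniform(-1, 1, size=(16, 16))
        f1 = rng.uniform(-1, 1, size=(16, 16))
        a = small_model.synthesize(f0, f1, 0.1)
        b = small_model.synthesize(f0, f1, 0.1)
        np.testing.assert_array_equal(a, b)

    def test_constant_inputs_reproduced(self, constant_model):
        # model trained on constant sequences reproduces held-out constants
        for c in (-0.4, 0.0, 0.6):
            f = np.full((32, 32), c)
            out = constant_model.synthesize(f, f, 0.0)
            assert np.abs(out - c).mean() < 0.05

    def test_trained_model_beats_linear_blend(self, trained_tiny, heldout_sequences):
        from angiosynth.metrics import compute_image_metrics
        from angiosynth.pipeline import linear_blend_interpolator

        model, _, _ = trained_tiny
        wins_model, wins_blend = [], []
        for seq in heldout_sequences[:10]:
            f = seq.frames
            t = 0.0  # midpoint of block (0, 6) at N=5 spacing
            gen = model.synthesize(f[0], f[6], t)
            blend = linear_blend_interpolator(f[0], f[6], t)
            real01 = (f[3] + 1) / 2
            wins_model.append(compute_image_metrics((gen + 1) / 2, real01)[0])
            wins_blend.append(compute_image_metrics((blend + 1) / 2, real01)[0])
        assert np.mean(wins_model) > np.mean(wins_blend)

    def test_time_symmetry_smoke_reported(self, small_model):
        # reported, not asserted: no architectural symmetry claim
        rng = np.random.default_rng(8)
        f0 = rng.uniform(-1, 1, size=(16, 16))
        f1 = rng.uniform(-1, 1, size=(16, 16))
        fwd = small_model.synthesize(f0, f1, 0.3)
        rev = small_model.synthesize(f1, f0, -0.3)
        mad = float(np.abs(fwd - rev).mean())
        assert np.isfinite(mad)


class TestCheckpoint:
    def test_roundtrip_identical_outputs(self, tmp_path, trained_tiny):
        model, _, cfg = trained_tiny
        path = tmp_path / "model.npz"
        save_checkpoint(model, path, epoch=cfg.total_epochs)
        loaded, meta = load_checkpoint(path)
        assert meta["epoch"] == cfg.total_epochs
        rng = np.random.default_rng(9)
        f0 = rng.uniform(-1, 1, size=(64, 64))
        f1 = rng.uniform(-1, 1, size=(64, 64))
        np.testing.assert_array_equal(
            model.synthesize(f0, f1, 0.2), loaded.synthesize(f0, f1, 0.2)
        )
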