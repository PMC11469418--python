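import numpy as np
import pytest

from cardiomar.core import BinaryMask, CTVolume
from cardiomar.inpainting import (
    InpaintConfig,
    InpaintingModel,
    InpaintingResults,
    Patch,
    _masked_l1_t,
    _tv_t,
    build_inpainter,
    extract_patches,
    inpaint,
    masked_l1,
    solid_fill,
    tv_on_difference,
)
from cardiomar.nnet import Tensor
from cardiomar.phantom import make_case


class TestSolidFill:
    def test_empty_mask_identity(self, rng):
        vol = CTVolume(rng.normal(size=(6, 6, 6)))
        out = solid_fill(vol, BinaryMask(np.zeros((6, 6, 6), bool)))
        np.testing.assert_array_equal(out.voxels, vol.voxels)

    def test_full_mask_constant(self, rng):
        vol = CTVolume(rng.normal(size=(5, 5, 5)))
        out = solid_fill(vol, BinaryMask(np.ones((5, 5, 5), bool)), fill_hu=-7.0)
        assert np.all(out.voxels == -7.0)

    def test_exact_voxel_count_changed(self, rng):
        vol = CTVolume(rng.normal(100, 10, size=(6, 6, 6)))
        m = np.zeros((6, 6, 6), bool)
        m[([0, 1, 2, 3, 4], [0, 1, 2, 3, 4], [0, 1, 2, 3, 4])] = True
        out = solid_fill(vol, BinaryMask(m), 0.0)
        assert int((out.voxels != vol.voxels).sum()) == 5


class TestLosses:
    def test_masked_l1_hand_value(self):
        pred = np.zeros((2, 2, 1))
        target = np.array([1.0, -2.0, 3.0, -4.0]).reshape(2, 2, 1)
        mask = np.ones((2, 2, 1), bool)
        assert masked_l1(pred, target, mask) == pytest.approx(2.5)

    def test_masked_l1_ignores_outside(self, rng):
        pred = rng.normal(size=(4, 4, 4))
        target = pred.copy()
        mask = np.zeros((4, 4, 4), bool)
        mask[1, 1, 1] = True
        target[3, 3, 3] += 100.0  # outside the mask
        assert masked_l1(pred, target, mask) == 0.0

    def test_masked_l1_empty_mask_warns_zero(self, rng):
        with pytest.warns(UserWarning, match="empty"):
            v = masked_l1(rng.normal(size=(3, 3, 3)),
                          rng.normal(size=(3, 3, 3)),
                          np.zeros((3, 3, 3), bool))
        assert v == 0.0

    def test_tv_zero_for_equal_and_constant_shift(self, rng):
        pred = rng.normal(size=(4, 4, 4))
        assert tv_on_difference(pred, pred) == 0.0
        assert tv_on_difference(pred, pred + 5.0) == pytest.approx(0.0, abs=1e-6)

    def test_tv_hand_value(self):
        pred = np.zeros((2, 2, 1))
        target = np.array([[0.0, 1.0], [0.0, 1.0]]).reshape(2, 2, 1)
        # forward differences: axis0 -> 0+0, axis1 -> 1+1 (sum 2 over 4 terms)
        assert tv_on_difference(pred, target) == pytest.approx(2.0 / 4.0)

    def test_graph_losses_match_numpy(self, rng):
        pred = rng.normal(size=(2, 1, 4, 4, 4)).astype(np.float32)
        target = rng.normal(size=(2, 1, 4, 4, 4)).astype(np.float32)
        mask = rng.random((2, 1, 4, 4, 4)) > 0.5
        l1_g = float(_masked_l1_t(Tensor(pred), Tensor(target), mask).data)
        l1_ref = np.abs(pred[mask] - target[mask]).mean()
        assert l1_g == pytest.approx(l1_ref, rel=1e-5)
        tv_g = float(_tv_t(Tensor(pred), Tensor(target)).data)
        tv_ref = np.mean(
            [tv_on_difference(pred[i, 0], target[i, 0]) for i in range(2)]
        )
        assert tv_g == pytest.approx(tv_ref, rel=1e-4)

    def test_weight_tie_doubles_objective(self, rng):
        """Doubling w_l1 (w_tv tied at half) doubles the non-adversarial
        generator objective on fixed tensors."""
        pred = Tensor(rng.normal(size=(1, 1, 4, 4, 4)).astype(np.float32))
        target = Tensor(rng.normal(size=(1, 1, 4, 4, 4)).astype(np.float32))
        mask = rng.random((1, 1, 4, 4, 4)) > 0.4

        def objective(w_l1):
            cfg = InpaintConfig.toy(w_l1=w_l1)
            assert cfg.w_tv == pytest.approx(0.5 * w_l1)
            return (
                cfg.w_l1 * float(_masked_l1_t(pred, target, mask).data)
                + cfg.w_tv * float(_tv_t(pred, target).data)
            )

        assert objective(200.0) == pytest.approx(2.0 * objective(100.0), rel=1e-6)


class TestConfig:
    def test_tv_defaults_to_half_l1(self):
        assert InpaintConfig(w_l1=40.0).w_tv == 20.0

    def test_patch_divisibility(self):
        with pytest.raises(ValueError, match="divisible"):
            InpaintConfig(patch_size=(30, 32, 16), enc_layers=4)

    def test_full_scale_parameter_count_near_4_8_million(self):
        gen, _ = build_inpainter(InpaintConfig())
        assert abs(gen.n_parameters() - 4.8e6) / 4.8e6 < 0.20

    def test_seeded_build_reproducible(self):
        g1, d1 = build_inpainter(InpaintConfig.toy(seed=3))
        g2, d2 = build_inpainter(InpaintConfig.toy(seed=3))
        for a, b in zip(g1.state_arrays(), g2.state_arrays()):
            np.testing.assert_array_equal(a, b)
        for a, b in zip(d1.state_arrays(), d2.state_arrays()):
            np.testing.assert_array_equal(a, b)


class TestExtractPatches:
    def test_small_artifact_single_patch_covers(self):
        case = make_case(17)
        cfg = InpaintConfig.toy()
        patches = extract_patches(case, cfg, seed=0)
        covered = np.zeros(case.clean.shape, bool)
        for p in patches:
            sl = tuple(slice(o, o + s) for o, s in zip(p.offset, cfg.patch_size))
            covered[sl] = True
        assert not np.any(case.artifact_mask.voxels & ~covered)

    @pytest.mark.parametrize("seed", range(0, 40, 2))
    def test_full_coverage_over_many_phantoms(self, seed):
        case = make_case(seed)
        cfg = InpaintConfig.toy()
        covered = np.zeros(case.clean.shape, bool)
        for p in extract_patches(case, cfg, seed=seed):
            sl = tuple(slice(o, o + s) for o, s in zip(p.offset, cfg.patch_size))
            covered[sl] = True
        assert not np.any(case.artifact_mask.voxels & ~covered)

    def test_channel_one_matches_target_outside_mask(self):
        case = make_case(21)
        for p in extract_patches(case, InpaintConfig.toy(), seed=1):
            outside = ~p.input_ch2
            np.testing.assert_array_equal(p.input_ch1[outside], p.target[outside])
            assert np.all(p.input_ch1[p.input_ch2] == 0.0)

    def test_same_seed_same_offsets(self):
        case = make_case(23)
        cfg = InpaintConfig.toy()
        o1 = [p.offset for p in extract_patches(case, cfg, seed=5)]
        o2 = [p.offset for p in extract_patches(case, cfg, seed=5)]
        assert o1 == o2

    def test_empty_mask_warns_empty_list(self):
        case = make_case(25)
        case.artifact_mask.voxels[:] = False
        with pytest.warns(UserWarning, match="empty"):
            assert extract_patches(case, InpaintConfig.toy(), seed=0) == []


class TestInpaintCompositing:
    def test_empty_mask_is_bit_identical_passthrough(self, rng):
        gen, _ = build_inpainter(InpaintConfig.toy(seed=1))
        vol = CTVolume(rng.normal(100, 300, size=(64, 64, 32)))
        out = inpaint(gen, vol, BinaryMask(np.zeros((64, 64, 32), bool)),
                      InpaintConfig.toy(seed=1))
        np.testing.assert_array_equal(out.voxels, vol.voxels)

    @pytest.mark.parametrize("seed", range(10))
    def test_untrained_generator_exact_outside_mask(self, seed):
        """Compositing contract: outside the mask the output equals the
        input exactly, whatever the generator weights."""
        case = make_case(seed)
        cfg = InpaintConfig.toy(seed=seed)
        gen, _ = build_inpainter(cfg)
        out = inpaint(gen, case.corrupted, case.artifact_mask, cfg)
        outside = ~case.artifact_mask.voxels
        np.testing.assert_array_equal(
            out.voxels[outside], case.corrupted.voxels[outside]
        )

    def test_output_stays_in_hu_window(self):
        case = make_case(3)
        cfg = InpaintConfig.toy(seed=3)
        gen, _ = build_inpainter(cfg)
        out = inpaint(gen, case.corrupted, case.artifact_mask, cfg)
        inside = case.artifact_mask.voxels
        assert out.voxels[inside].min() >= cfg.hu_window[0]
        assert out.voxels[inside].max() <= cfg.hu_window[1]


@pytest.fixture(scope="module")
def tiny_patches():
    cases = [make_case(s) for s in (31, 32)]
    cfg = InpaintConfig.toy()
    patches = []
    for c in cases:
        patches.extend(extract_patches(c, cfg, seed=c.seed)[:2])
    return patches


class TestTraining:
    def test_short_training_reduces_masked_l1(self, tiny_patches):
        cfg = InpaintConfig.toy(seed=7, epochs=6)
        res = InpaintingModel(tiny_patches, cfg).fit()
        assert res.history["g_l1"][-1] < res.history["g_l1"][0]

    def test_pure_regression_ablation_still_learns(self, tiny_patches):
        cfg = InpaintConfig.toy(seed=7, epochs=4, w_adv=0.0)
        res = InpaintingModel(tiny_patches, cfg).fit()
        assert res.history["g_l1"][-1] < res.history["g_l1"][0]

    def test_same_seed_identical_histories(self, tiny_patches):
        cfg = InpaintConfig.toy(seed=9, epochs=2)
        h1 = InpaintingModel(tiny_patches, cfg).fit().history
        h2 = InpaintingModel(tiny_patches, cfg).fit().history
        assert h1 == h2

    def test_all_empty_masks_rejected(self, rng):
        p = Patch(
            input_ch1=rng.normal(size=(32, 32, 16)).astype(np.float32),
            input_ch2=np.zeros((32, 32, 16), bool),
            target=rng.normal(size=(32, 32, 16)).astype(np.float32),
            offset=(0, 0, 0),
        )
        with pytest.raises(ValueError, match="no artifact voxels"):
            InpaintingModel([p], InpaintConfig.toy())

    def test_save_load_round_trip(self, tiny_patches, tmp_path):
        cfg = InpaintConfig.toy(seed=5, epochs=1)
        res = InpaintingModel(tiny_patches, cfg).fit()
        res.save(tmp_path / "inp")
        back = InpaintingResults.load(tmp_path / "inp")
        case = make_case(33)
        a = res.inpaint(case.corrupted, case.artifact_mask)
        b = back.inpaint(case.corrupted, case.artifact_mask)
        np.testing.assert_array_equal(a.voxels, b.voxels)
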