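import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from oracles import (
    brute_dice,
    brute_surface_dice,
    brute_surface_distances,
    random_blob,
)

from cardiomar.core import BinaryMask, CTVolume
from cardiomar.evaluation import (
    detection_report,
    dice,
    masked_ssim,
    reference_segmenter,
    surface_dice,
    surface_distances,
    three_arm_comparison,
    tnr_margin,
    tpr_eroded,
    _match_components,
)
from cardiomar.phantom import make_case


def _mask(arr, spacing=(1.0, 1.0, 1.0)):
    return BinaryMask(np.asarray(arr, bool), spacing)


def _cube(shape, sl):
    m = np.zeros(shape, bool)
    m[sl] = True
    return m


class TestDice:
    def test_identical_nonempty(self):
        a = _mask(_cube((8, 8, 8), (slice(2, 5),) * 3))
        assert dice(a, a) == 1.0

    def test_disjoint(self):
        a = _mask(_cube((8, 8, 8), (slice(0, 2),) * 3))
        b = _mask(_cube((8, 8, 8), (slice(5, 8),) * 3))
        assert dice(a, b) == 0.0

    def test_hand_counts(self):
        a = np.zeros((5, 5, 5), bool)
        b = np.zeros((5, 5, 5), bool)
        a.ravel()[:9] = True
        b.ravel()[3:9] = True  # |a|=9, |b|=6, |a∩b|=6
        assert dice(_mask(a), _mask(b)) == pytest.approx(0.8)

    def test_both_empty_convention(self):
        e = _mask(np.zeros((4, 4, 4), bool))
        assert dice(e, e) == 1.0

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError):
            dice(_mask(np.zeros((4, 4, 4), bool)),
                 _mask(np.zeros((5, 4, 4), bool)))


class TestSurfaceDice:
    def test_identical(self):
        a = _mask(_cube((10, 10, 10), (slice(2, 7),) * 3))
        assert surface_dice(a, a, 3) == 1.0

    def test_offset_cubes_within_tolerance(self):
        a = _mask(_cube((12, 12, 12), (slice(2, 7),) * 3))
        b = _mask(_cube((12, 12, 12), (slice(3, 8),) * 3))
        assert surface_dice(a, b, 3) == 1.0

    def test_distant_voxels_zero(self):
        a = np.zeros((15, 15, 15), bool)
        b = np.zeros((15, 15, 15), bool)
        a[1, 1, 1] = True
        b[11, 1, 1] = True
        assert surface_dice(_mask(a), _mask(b), 3) == 0.0

    def test_empty_conventions(self):
        e = _mask(np.zeros((5, 5, 5), bool))
        a = _mask(_cube((5, 5, 5), (slice(1, 3),) * 3))
        assert surface_dice(e, e) == 1.0
        assert surface_dice(a, e) == 0.0


class TestSurfaceDistances:
    def test_identical_all_zero(self):
        a = _mask(_cube((8, 8, 8), (slice(2, 6),) * 3), spacing=(1.5, 1.5, 1.5))
        assert surface_distances(a, a) == (0.0, 0.0, 0.0)

    def test_single_voxel_pair_345(self):
        a = np.zeros((8, 8, 8), bool)
        b = np.zeros((8, 8, 8), bool)
        a[0, 0, 0] = True
        b[3, 4, 0] = True
        msd, hd, hd95 = surface_distances(_mask(a), _mask(b))
        assert (msd, hd, hd95) == (5.0, 5.0, 5.0)

    def test_symmetry(self, rng):
        a = _mask(random_blob(rng, (12, 12, 12)))
        b = _mask(random_blob(rng, (12, 12, 12)))
        assert surface_distances(a, b) == surface_distances(b, a)

    def test_spacing_scales_to_mm(self):
        a = np.zeros((8, 8, 8), bool)
        b = np.zeros((8, 8, 8), bool)
        a[0, 0, 0] = True
        b[0, 0, 2] = True
        msd, hd, _ = surface_distances(_mask(a, (1, 1, 1.5)), _mask(b, (1, 1, 1.5)))
        assert hd == pytest.approx(3.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            surface_distances(_mask(np.zeros((4, 4, 4), bool)),
                              _mask(np.ones((4, 4, 4), bool)))


class TestDetectionRates:
    def test_perfect_prediction(self):
        manual = _mask(_cube((12, 12, 12), (slice(2, 10),) * 3))
        assert tpr_eroded(manual, manual, 3) == 1.0
        assert tnr_margin(manual, manual, 3) == 1.0

    def test_empty_prediction(self):
        manual = _mask(_cube((12, 12, 12), (slice(2, 10),) * 3))
        empty = _mask(np.zeros((12, 12, 12), bool))
        assert tpr_eroded(empty, manual, 3) == 0.0

    def test_seven_cube_erodes_to_single_voxel(self):
        manual = _mask(_cube((11, 11, 11), (slice(2, 9),) * 3))
        core = _mask(_cube((11, 11, 11), (slice(5, 6),) * 3))
        assert tpr_eroded(core, manual, 3) == 1.0

    def test_eroded_away_is_nan(self):
        manual = _mask(_cube((8, 8, 8), (slice(2, 4),) * 3))
        assert np.isnan(tpr_eroded(manual, manual, 3))

    def test_full_grid_prediction_tnr_zero(self):
        manual = _mask(_cube((10, 10, 10), (slice(4, 6),) * 3))
        full = _mask(np.ones((10, 10, 10), bool))
        assert tnr_margin(full, manual, 3) == 0.0

    def test_tnr_hand_count(self):
        manual = np.zeros((10, 10, 10), bool)
        manual[5, 5, 5] = True
        pred = np.zeros((10, 10, 10), bool)
        pred[0, 0, 0] = pred[0, 0, 1] = pred[9, 9, 9] = pred[0, 9, 0] = pred[9, 0, 0] = True
        ball = sum(
            1
            for x in range(10) for y in range(10) for z in range(10)
            if (x - 5) ** 2 + (y - 5) ** 2 + (z - 5) ** 2 <= 9
        )
        n_neg = 1000 - ball
        assert tnr_margin(_mask(pred), _mask(manual), 3) == pytest.approx(
            1 - 5 / n_neg
        )

    def test_detection_report_keys(self):
        manual = _mask(_cube((12, 12, 12), (slice(2, 10),) * 3))
        rep = detection_report(manual, manual)
        assert rep == {"dice": 1.0, "tpr": 1.0, "tnr": 1.0}


class TestMaskedSSIM:
    def test_identical_is_one(self, rng):
        vol = CTVolume(rng.normal(100, 200, size=(16, 16, 16)))
        m = _mask(_cube((16, 16, 16), (slice(4, 12),) * 3))
        assert masked_ssim(vol, vol, m) == pytest.approx(1.0)

    def test_large_offset_penalized(self, rng):
        truth = CTVolume(rng.normal(100, 200, size=(16, 16, 16)))
        pred = CTVolume(truth.voxels + 2500.0)
        m = _mask(np.ones((16, 16, 16), bool))
        assert masked_ssim(pred, truth, m) < 0.5

    def test_masking_contract_interior_window(self, rng):
        """Corrupting the prediction far outside the mask leaves the
        masked mean unchanged when the window cannot reach the change."""
        truth = CTVolume(rng.normal(100, 200, size=(24, 24, 24)))
        pred = truth.copy()
        m = np.zeros((24, 24, 24), bool)
        m[2:6, 2:6, 2:6] = True
        base = masked_ssim(pred, truth, _mask(m))
        pred.voxels[18:, 18:, 18:] += 1000.0  # > 11 voxels from the mask
        assert masked_ssim(pred, truth, _mask(m)) == pytest.approx(base)

    def test_empty_mask_rejected(self, rng):
        vol = CTVolume(rng.normal(size=(12, 12, 12)))
        with pytest.raises(ValueError):
            masked_ssim(vol, vol, _mask(np.zeros((12, 12, 12), bool)))


class TestAgainstBruteForce:
    """EDT-based implementations agree with all-pairs/set-logic oracles."""

    @pytest.mark.parametrize("seed", range(8))
    def test_random_masks(self, seed):
        g = np.random.default_rng(seed)
        shape = tuple(g.integers(8, 15, size=3))
        a = random_blob(g, shape)
        b = random_blob(g, shape)
        spacing = tuple(g.uniform(0.5, 2.0, size=3))
        A, B = BinaryMask(a, spacing), BinaryMask(b, spacing)
        assert dice(A, B) == pytest.approx(brute_dice(a, b), abs=1e-12)
        assert surface_dice(A, B, 3) == pytest.approx(
            brute_surface_dice(a, b, 3), abs=1e-12
        )
        got = surface_distances(A, B)
        want = brute_surface_distances(a, b, spacing)
        assert got == pytest.approx(want, abs=1e-9)

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 5000))
    def test_invariants(self, seed):
        g = np.random.default_rng(seed)
        a = random_blob(g, (10, 10, 10))
        b = random_blob(g, (10, 10, 10))
        A, B = BinaryMask(a), BinaryMask(b)
        msd, hd, hd95 = surface_distances(A, B)
        assert 0 <= msd <= hd and hd95 <= hd
        assert 0.0 <= surface_dice(A, B, 2) <= 1.0
        # simultaneous translation leaves every metric unchanged
        at = np.roll(a, 2, axis=0)
        bt = np.roll(b, 2, axis=0)
        if not (a[-2:].any() or b[-2:].any()):
            At, Bt = BinaryMask(at), BinaryMask(bt)
            assert dice(At, Bt) == pytest.approx(dice(A, B))
            assert surface_distances(At, Bt) == pytest.approx((msd, hd, hd95))


class TestReferenceSegmenter:
    def test_clean_phantom_high_dice(self):
        case = make_case(42)
        comps = reference_segmenter(case.clean, case.heart_mask)
        assigned = _match_components(comps, case.chamber_masks)
        scores = [
            dice(BinaryMask.like(case.heart_mask, assigned[k]), ch)
            for k, ch in case.chamber_masks.items()
        ]
        assert min(scores) > 0.95

    def test_corruption_lowers_mean_dice(self):
        case = make_case(43)

        def mean_dice(vol):
            comps = reference_segmenter(vol, case.heart_mask)
            assigned = _match_components(comps, case.chamber_masks)
            return np.mean([
                dice(BinaryMask.like(case.heart_mask, assigned[k]), ch)
                for k, ch in case.chamber_masks.items()
            ])

        assert mean_dice(case.corrupted) < mean_dice(case.clean)

    def test_deterministic(self):
        case = make_case(44)
        a = reference_segmenter(case.corrupted, case.heart_mask)
        b = reference_segmenter(case.corrupted, case.heart_mask)
        assert set(a) == set(b)
        for k in a:
            np.testing.assert_array_equal(a[k].voxels, b[k].voxels)

    def test_no_components_empty_dict(self):
        vol = CTVolume(np.zeros((16, 16, 16)))
        heart = _mask(_cube((16, 16, 16), (slice(4, 12),) * 3))
        assert reference_segmenter(vol, heart) == {}

    def test_marker_mode_splits_bridged_pools(self):
        vol = np.zeros((20, 20, 8))
        vol[2:8, 4:16, 2:6] = 300.0
        vol[12:18, 4:16, 2:6] = 300.0
        vol[8:12, 9:11, 3:5] = 300.0  # thin bridge between the two pools
        heart = _mask(np.ones((20, 20, 8), bool))
        segs = reference_segmenter(
            CTVolume(vol), heart,
            markers={1: (5, 10, 4), 2: (15, 10, 4)},
        )
        assert segs[1].count() > 0 and segs[2].count() > 0
        assert not np.any(segs[1].voxels & segs[2].voxels)


class TestThreeArm:
    def test_ground_truth_arm_is_perfect(self):
        case = make_case(55)
        case.corrupted = case.clean.copy()  # "uncorrected" arm is the truth
        rep = three_arm_comparison([case], inpaint_results=None)
        rows = rep.rows
        unc = rows[(rows.arm == "uncorrected") & (rows.structure != "(image)")]
        assert np.all(unc["dice"] == 1.0)
        assert np.all(unc["hd_mm"] == 0.0)

    def test_row_count_affected_chambers_times_arms(self):
        case = make_case(56)
        affected = [
            k for k, ch in case.chamber_masks.items()
            if (ch.voxels & case.artifact_mask.voxels).any()
        ]
        rep = three_arm_comparison([case], inpaint_results=None)
        rows = rep.rows[rep.rows.structure != "(image)"]
        assert len(rows) == 2 * len(affected)  # two arms without a model
        assert set(rows.structure) == {f"chamber_{k}" for k in affected}

    def test_aggregate_orders_arms(self):
        case = make_case(57)
        rep = three_arm_comparison([case], inpaint_results=None)
        agg = rep.aggregate()
        assert list(agg.index) == ["uncorrected", "solid_fill"]

    def test_csv_long_format(self, tmp_path):
        case = make_case(58)
        rep = three_arm_comparison([case], inpaint_results=None)
        out = tmp_path / "m.csv"
        rep.to_csv(out)
        import pandas as pd

        df = pd.read_csv(out)
        assert set(df.columns) == {"case", "structure", "arm", "metric", "value"}
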