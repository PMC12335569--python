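import numpy as np
import pytest

from strokekit.instances import label_components
from strokekit.seg_metrics import (
    ald,
    avd,
    dice,
    evaluate_case,
    false_positive_volume_ml,
    lesionwise_f1,
    stratify_by_size,
)
from strokekit.synth_fixtures import PhantomSpec, make_phantom
from strokekit.volumes_io import LesionMask
from conftest import cube_mask, mask_from, random_mask
from oracles import f1_by_overlap_matrix, flood_fill_components


def two_gt_three_pred():
    """2 GT lesions; 3 predicted: two hit distinct GT lesions, one touches nothing."""
    gt = cube_mask((20, 20, 20), [((1, 1, 1), 3), ((10, 10, 10), 3)])
    pred = cube_mask((20, 20, 20), [((2, 2, 2), 2), ((11, 11, 11), 2), ((16, 1, 16), 2)])
    return pred, gt


class TestDice:
    def test_identical_masks(self, rng):
        m = random_mask(rng, density=0.3)
        assert dice(m, m) == 1.0

    def test_disjoint_masks(self):
        a = cube_mask((10, 10, 10), [((0, 0, 0), 3)])
        b = cube_mask((10, 10, 10), [((6, 6, 6), 3)])
        assert dice(a, b) == 0.0

    def test_constructed_overlap(self):
        # |pred| = 8, |gt| = 4, intersection 4 -> 2*4/12
        pred = cube_mask((10, 10, 10), [((1, 1, 1), 2)])
        gt_vol = np.zeros((10, 10, 10))
        gt_vol[1:3, 1:3, 1] = 1  # 4 voxels, all inside pred
        gt = mask_from(gt_vol)
        assert pred.foreground_voxels == 8 and gt.foreground_voxels == 4
        assert dice(pred, gt) == pytest.approx(2 * 4 / 12)

    def test_both_empty_convention(self):
        e = mask_from(np.zeros((5, 5, 5)))
        assert dice(e, e) == 1.0

    def test_empty_vs_nonempty(self):
        e = mask_from(np.zeros((10, 10, 10)))
        m = cube_mask((10, 10, 10), [((1, 1, 1), 2)])
        assert dice(e, m) == 0.0

    def test_symmetric(self, rng):
        a, b = random_mask(rng), random_mask(rng)
        assert dice(a, b) == dice(b, a)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice(mask_from(np.zeros((5, 5, 5))), mask_from(np.zeros((6, 6, 6))))


class TestAvd:
    def test_formula(self):
        # 10.0 ml vs 7.5 ml at 1 mm iso
        va = np.zeros((30, 30, 30)); va.ravel()[:10000] = 1
        vb = np.zeros((30, 30, 30)); vb.ravel()[:7500] = 1
        assert avd(mask_from(va), mask_from(vb)) == pytest.approx(2.5)

    def test_identical_masks_zero(self, rng):
        m = random_mask(rng)
        assert avd(m, m) == 0.0

    def test_empty_vs_lesion(self):
        v = np.zeros((20, 20, 20)); v.ravel()[:3200] = 1
        assert avd(mask_from(np.zeros((20, 20, 20))), mask_from(v)) == pytest.approx(3.2)

    def test_symmetric(self, rng):
        a, b = random_mask(rng), random_mask(rng)
        assert avd(a, b) == avd(b, a)


class TestAld:
    def test_three_vs_five(self):
        pred = cube_mask((30, 30, 30), [((i * 6, 1, 1), 2) for i in range(3)])
        gt = cube_mask((30, 30, 30), [((i * 6, 10, 10), 2) for i in range(5)])
        assert ald(pred, gt) == 2

    def test_both_empty(self):
        e = mask_from(np.zeros((5, 5, 5)))
        assert ald(e, e) == 0

    def test_connectivity_dependence_at_corner_contact(self):
        # two predicted cubes touching at a corner vs 2 separated GT cubes
        pred = cube_mask((12, 12, 12), [((1, 1, 1), 3), ((4, 4, 4), 3)])
        gt = cube_mask((12, 12, 12), [((1, 1, 1), 3), ((8, 8, 8), 3)])
        assert ald(pred, gt, connectivity=26) == 1
        assert ald(pred, gt, connectivity=6) == 0


class TestLesionwiseF1:
    def test_constructed_two_gt_three_pred(self):
        pred, gt = two_gt_three_pred()
        f1, tp, fp, fn = lesionwise_f1(pred, gt)
        assert (tp, fp, fn) == (2, 1, 0)
        assert f1 == pytest.approx(0.8)

    def test_perfect_prediction(self):
        gt = cube_mask((30, 30, 30), [((i * 7, 1, 1), 3) for i in range(4)])
        f1, tp, fp, fn = lesionwise_f1(gt, gt)
        assert (f1, tp, fp, fn) == (1.0, 4, 0, 0)

    def test_empty_prediction_misses_all(self):
        gt = cube_mask((20, 20, 20), [((1, 1, 1), 3), ((10, 10, 10), 3)])
        f1, tp, fp, fn = lesionwise_f1(mask_from(np.zeros((20, 20, 20))), gt)
        assert (f1, tp, fp, fn) == (0.0, 0, 0, 2)

    def test_both_empty_convention(self):
        e = mask_from(np.zeros((5, 5, 5)))
        assert lesionwise_f1(e, e) == (1.0, 0, 0, 0)

    def test_one_pred_blob_covering_two_gt_lesions(self):
        gt = cube_mask((20, 20, 20), [((2, 2, 2), 2), ((8, 8, 8), 2)])
        pred = cube_mask((20, 20, 20), [((1, 1, 1), 10)])
        f1, tp, fp, fn = lesionwise_f1(pred, gt)
        assert (tp, fp, fn) == (2, 0, 0)
        assert f1 == 1.0

    def test_swap_exchanges_fp_fn(self, rng):
        a, b = random_mask(rng, density=0.1), random_mask(rng, density=0.1)
        f1_ab, tp_ab, fp_ab, fn_ab = lesionwise_f1(a, b)
        f1_ba, tp_ba, fp_ba, fn_ba = lesionwise_f1(b, a)
        assert (fp_ab, fn_ab) == (fn_ba, fp_ba)
        assert f1_ab == pytest.approx(f1_ba)

    def test_oracle_equivalence_on_random_phantoms(self, rng):
        """F1 matches the exhaustive instance-overlap-matrix oracle."""
        for _ in range(30):
            pred = random_mask(rng, shape=(10, 10, 10), density=rng.uniform(0.05, 0.3))
            gt = random_mask(rng, shape=(10, 10, 10), density=rng.uniform(0.05, 0.3))
            got = lesionwise_f1(pred, gt)
            expected = f1_by_overlap_matrix(
                flood_fill_components(pred.voxels, 26),
                flood_fill_components(gt.voxels, 26),
            )
            assert got[1:] == expected[1:]
            assert got[0] == pytest.approx(expected[0])


class TestEvaluateCase:
    def test_identical_masks(self):
        gt = cube_mask((20, 20, 20), [((1, 1, 1), 3), ((10, 10, 10), 3)])
        cm = evaluate_case(gt, gt)
        assert (cm.dsc, cm.lesion_f1, cm.avd_ml, cm.ald) == (1.0, 1.0, 0.0, 0)
        assert (cm.tp_lesions, cm.fp_lesions, cm.fn_lesions) == (2, 0, 0)

    def test_both_empty(self):
        e = mask_from(np.zeros((5, 5, 5)))
        cm = evaluate_case(e, e)
        assert (cm.dsc, cm.lesion_f1, cm.avd_ml, cm.ald) == (1.0, 1.0, 0.0, 0)

    def test_composes_component_metrics(self):
        pred, gt = two_gt_three_pred()
        cm = evaluate_case(pred, gt)
        assert cm.dsc == pytest.approx(dice(pred, gt))
        assert cm.lesion_f1 == pytest.approx(0.8)
        assert cm.avd_ml == pytest.approx(avd(pred, gt))
        assert cm.ald == ald(pred, gt)

    def test_deleting_one_lesion_moves_each_metric_predictably(self):
        gt, labeling = make_phantom(PhantomSpec(shape=(48, 48, 48), lesion_count=3,
                                                volume_median_ml=1.0, seed=11))
        # delete the smallest lesion from the prediction, change nothing else
        smallest = labeling.per_instance.iloc[-1]
        pred_vox = gt.voxels.copy()
        pred_vox[labeling.labels == smallest["instance_id"]] = 0
        pred = LesionMask(geometry=gt.geometry, voxels=pred_vox)
        cm = evaluate_case(pred, gt)
        assert cm.ald == 1
        assert cm.fn_lesions == 1 and cm.fp_lesions == 0
        assert cm.avd_ml == pytest.approx(smallest["volume_ml"])


class TestFalsePositiveVolume:
    def test_disjoint_fp_blob(self):
        gt = cube_mask((30, 30, 30), [((1, 1, 1), 5)])
        extra = np.zeros((30, 30, 30)); extra.ravel()[20000:22000] = 1
        pred = mask_from(np.maximum(gt.voxels, mask_from(extra).voxels))
        assert false_positive_volume_ml(pred, gt) == pytest.approx(2.0)


class TestStratifyBySize:
    def test_boundary_volumes_bin_upward(self):
        cm = evaluate_case(mask_from(np.zeros((3, 3, 3))), mask_from(np.zeros((3, 3, 3))))
        table = stratify_by_size([(cm, 1.0), (cm, 5.0), (cm, 20.0)])
        assert table["n_cases"].tolist() == [1, 1, 1]

    def test_all_small(self):
        cm = evaluate_case(mask_from(np.zeros((3, 3, 3))), mask_from(np.zeros((3, 3, 3))))
        table = stratify_by_size([(cm, 0.1)] * 4)
        assert table["n_cases"].tolist() == [4, 0, 0]

    def test_median_iqr_match_order_statistics(self):
        from strokekit.seg_metrics import CaseMetrics

        cms = [CaseMetrics(dsc=d, lesion_f1=1.0, avd_ml=0.0, ald=0,
                           tp_lesions=1, fp_lesions=0, fn_lesions=0)
               for d in (0.4, 0.9, 0.2)]
        table = stratify_by_size([(cm, 1.0) for cm in cms])
        row = table[table["size_bin"] == "<5 ml"].iloc[0]
        # sorted dsc [0.2, 0.4, 0.9]: median 0.4; linearly interpolated
        # quartiles 0.3 and 0.65 give IQR 0.35
        assert row["dsc_median"] == pytest.approx(0.4)
        assert row["dsc_iqr"] == pytest.approx(0.35)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            stratify_by_size([])
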