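import numpy as np
import pytest

from patchbleed.errors import DataError
from patchbleed.inference import LesionMap, label_components
from patchbleed.metrics import (
    ConfusionCounts,
    LesionMatchResult,
    confusion_from_predictions,
    evaluate_cohort,
    lesion_metrics,
    match_lesions,
    patch_metrics,
)
from patchbleed.volume_io import Tissue


def random_lesion_map(rng, shape=(16, 16, 8), n_blobs=3):
    grid = np.zeros(shape, dtype=bool)
    for _ in range(n_blobs):
        c = rng.integers(2, np.array(shape) - 2)
        r = rng.integers(1, 3)
        idx = np.indices(shape)
        grid |= sum((g - cc) ** 2 for g, cc in zip(idx, c)) <= r * r
    return label_components(grid)


def brute_force_match(auto: LesionMap, manual: LesionMap):
    auto_sets = {i: set(map(tuple, v)) for i, v in auto.lesions.items()}
    man_sets = {i: set(map(tuple, v)) for i, v in manual.lesions.items()}
    pairs = {
        (a, m)
        for a, sa in auto_sets.items()
        for m, sm in man_sets.items()
        if sa & sm
    }
    tp = len({m for _a, m in pairs})
    fp = len(auto_sets) - len({a for a, _m in pairs})
    fn = len(man_sets) - tp
    return tp, fp, fn, sorted(pairs)


class TestPatchMetrics:
    def test_hand_computed_example(self):
        acc, sens, spec = patch_metrics(ConfusionCounts(TP=3, TN=5, FP=1, FN=1))
        assert acc == pytest.approx(0.8)
        assert sens == pytest.approx(0.75)
        assert spec == pytest.approx(5 / 6)

    def test_perfect_classifier(self):
        assert patch_metrics(ConfusionCounts(TP=4, TN=6, FP=0, FN=0)) == (1.0, 1.0, 1.0)

    def test_empty_positive_class_flagged_not_zero(self):
        with pytest.warns(UserWarning, match="sensitivity undefined"):
            _acc, sens, _spec = patch_metrics(ConfusionCounts(TP=0, TN=5, FP=1, FN=0))
        assert np.isnan(sens)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(DataError):
            patch_metrics(ConfusionCounts(TP=0, TN=0, FP=0, FN=0))

    def test_negative_counts_rejected(self):
        with pytest.raises(DataError):
            ConfusionCounts(TP=-1, TN=0, FP=0, FN=0)

    def test_confusion_from_predictions(self):
        c = confusion_from_predictions([1, 1, 0, 0, 1], [1, 0, 0, 1, 1])
        assert (c.TP, c.TN, c.FP, c.FN) == (2, 1, 1, 1)


class TestMatchLesions:
    def test_identical_maps(self):
        m = random_lesion_map(np.random.default_rng(0))
        r = match_lesions(m, m)
        assert (r.TP, r.FP, r.FN) == (m.n_lesions, 0, 0)

    def test_single_voxel_overlap_counts_as_detected(self):
        a = np.zeros((8, 8, 4), dtype=bool)
        b = np.zeros((8, 8, 4), dtype=bool)
        a[2:4, 2:4, 1] = True
        b[3:6, 3:6, 1] = True  # overlaps a at exactly (3, 3, 1)
        r = match_lesions(label_components(a), label_components(b))
        assert (r.TP, r.FP, r.FN) == (1, 0, 0)

    def test_fully_disjoint_maps(self):
        a = np.zeros((12, 12, 6), dtype=bool)
        b = np.zeros((12, 12, 6), dtype=bool)
        a[1, 1, 1] = a[10, 10, 4] = True
        b[1, 5, 1] = b[5, 1, 2] = b[10, 5, 4] = True
        r = match_lesions(label_components(a), label_components(b))
        assert (r.TP, r.FP, r.FN) == (0, 2, 3)

    def test_one_auto_covering_two_manual_gives_two_tps(self):
        auto = np.zeros((12, 6, 4), dtype=bool)
        manual = np.zeros((12, 6, 4), dtype=bool)
        auto[2:10, 2, 2] = True
        manual[2, 2, 2] = manual[9, 2, 2] = True
        r = match_lesions(label_components(auto), label_components(manual))
        assert (r.TP, r.FP, r.FN) == (2, 0, 0)

    def test_matches_brute_force_on_random_maps(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            auto = random_lesion_map(rng, n_blobs=int(rng.integers(0, 4)))
            manual = random_lesion_map(rng, n_blobs=int(rng.integers(0, 4)))
            r = match_lesions(auto, manual)
            tp, fp, fn, pairs = brute_force_match(auto, manual)
            assert (r.TP, r.FP, r.FN) == (tp, fp, fn)
            assert r.matched_pairs == pairs

    def test_grid_mismatch_rejected(self):
        a = label_components(np.zeros((4, 4, 4), dtype=bool))
        b = label_components(np.zeros((5, 5, 5), dtype=bool))
        with pytest.raises(DataError):
            match_lesions(a, b)


class TestLesionMetrics:
    def test_hand_computed_example(self):
        sens, prec, dice = lesion_metrics(LesionMatchResult(TP=2, FN=1, FP=3))
        assert sens == pytest.approx(2 / 3)
        assert prec == pytest.approx(0.4)
        assert dice == pytest.approx(0.5)

    def test_perfect_agreement(self):
        assert lesion_metrics(LesionMatchResult(TP=5, FN=0, FP=0)) == (1.0, 1.0, 1.0)

    def test_both_empty_defined_as_perfect(self):
        assert lesion_metrics(LesionMatchResult(TP=0, FN=0, FP=0)) == (1.0, 1.0, 1.0)

    def test_no_shared_detections(self):
        sens, prec, dice = lesion_metrics(LesionMatchResult(TP=0, FN=2, FP=3))
        assert (sens, prec, dice) == (0.0, 0.0, 0.0)

    def test_dice_is_harmonic_mean_of_sensitivity_and_precision(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            tp, fn, fp = (int(x) for x in rng.integers(0, 20, 3))
            if tp + fn == 0 or tp + fp == 0:
                continue
            sens, prec, dice = lesion_metrics(LesionMatchResult(TP=tp, FN=fn, FP=fp))
            if sens + prec > 0:
                assert dice == pytest.approx(2 * sens * prec / (sens + prec))
            else:
                assert dice == 0.0


class TestEvaluateCohort:
    def test_identical_maps_give_unit_metrics(self, case):
        m = label_components(case.microbleed_gt)
        report = evaluate_cohort([(m, m, case.tissue_labels)])
        table = report.lesion_table
        overall = table[(table.scope == "overall")]
        assert (overall.sensitivity == 1.0).all()
        assert (overall.dice == 1.0).all()

    def test_pooled_and_per_subject_differ_for_unequal_cases(self):
        # case A: 1 manual lesion, detected; case B: 3 manual lesions, none detected
        def maps(n_manual, detected):
            manual = np.zeros((12, 12, 4), dtype=bool)
            for i in range(n_manual):
                manual[1 + 3 * i, 1, 1] = True
            auto = np.zeros_like(manual)
            if detected:
                auto[1, 1, 1] = True
            return label_components(auto), label_components(manual)

        tissue = np.full((12, 12, 4), int(Tissue.WM), dtype=np.int16)
        a_auto, a_manual = maps(1, True)
        b_auto, b_manual = maps(3, False)
        report = evaluate_cohort(
            [(a_auto, a_manual, tissue), (b_auto, b_manual, tissue)], per_region=False
        )
        t = report.lesion_table.set_index("aggregation")
        # pooled: TP=1 of 4 manual lesions -> 0.25; per-subject mean: (1 + 0)/2 = 0.5
        assert t.loc["pooled", "sensitivity"] == pytest.approx(0.25)
        assert t.loc["per_subject_mean", "sensitivity"] == pytest.approx(0.5)

    def test_region_without_lesions_flagged_empty(self, case):
        m = label_components(case.microbleed_gt)
        table = evaluate_cohort([(m, m, case.tissue_labels)]).lesion_table
        empty_rows = table[table.no_lesions]
        assert set(empty_rows.scope) <= {t.name for t in (
            Tissue.CORTICAL_GM, Tissue.DEEP_GM, Tissue.WM,
            Tissue.CEREBELLAR_GM, Tissue.CEREBELLAR_WM)}
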