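"""Evaluation statistics: binary metrics, McNemar, IoU/Dice, risk confusion."""

import numpy as np
import pytest

from cacvit.metrics_report import (
    ConfusionMatrix2,
    artery_detection_metrics,
    binary_metrics,
    iou_dice,
    mcnemar_test,
    reduction_percent,
    risk_confusion,
    round2,
)


class TestBinaryMetrics:
    def test_perfect_predictor(self):
        m = binary_metrics(ConfusionMatrix2(tn=10, fp=0, fn=0, tp=5))
        assert all(v == 1.0 for v in m.values())

    def test_zero_denominator_is_nan_not_zero(self):
        m = binary_metrics(ConfusionMatrix2(tn=5, fp=0, fn=0, tp=0))
        assert np.isnan(m["sensitivity"])
        assert np.isnan(m["precision_class1"])
        assert round2(m)["sensitivity"] == "n/a"

    def test_from_predictions(self):
        cm = ConfusionMatrix2.from_predictions([0, 0, 1, 1], [0, 1, 0, 1])
        assert (cm.tn, cm.fp, cm.fn, cm.tp) == (1, 1, 1, 1)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix2(tn=0, fp=0, fn=0, tp=0)


class TestReductionPercent:
    def test_identity_is_zero(self):
        assert reduction_percent(42, 42) == 0.0

    def test_known_reductions(self):
        assert reduction_percent(76, 39) == pytest.approx(48.68, abs=0.01)
        assert reduction_percent(446, 193) == pytest.approx(56.73, abs=0.01)

    def test_zero_before_rejected(self):
        with pytest.raises(ValueError):
            reduction_percent(0, 0)


class TestMcNemar:
    def test_no_discordance_degenerate(self):
        y = [0, 1, 0, 1]
        res = mcnemar_test(y, y, y)
        assert res["p_value"] == 1.0 and res["degenerate"]

    def test_one_sided_discordance_exact_binomial(self):
        # b=10, c=0: exact p = 2 * 0.5^10
        y = [1] * 10
        a = [1] * 10            # all correct
        b = [0] * 10            # all wrong
        res = mcnemar_test(y, a, b)
        assert res["b"] == 10 and res["c"] == 0
        assert res["exact"]
        assert res["p_value"] == pytest.approx(2 * 0.5 ** 10, rel=1e-12)

    def test_matches_statsmodels_exact(self):
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, size=30)
        pa = rng.integers(0, 2, size=30)
        pb = rng.integers(0, 2, size=30)
        res = mcnemar_test(y, pa, pb)
        from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

        table = np.array([[0, res["b"]], [res["c"], 0]])
        sm = sm_mcnemar(table, exact=res["exact"], correction=True)
        assert res["p_value"] == pytest.approx(sm.pvalue, rel=1e-6)

    def test_balanced_discordance_continuity_corrected(self):
        # b = c = 15 -> chi-square branch, statistic (|0|-1)^2 / 30
        y = np.zeros(60, dtype=int)
        pa = np.concatenate([np.ones(15), np.zeros(45)]).astype(int)
        pb = np.concatenate([np.zeros(15), np.ones(15), np.zeros(30)]).astype(int)
        res = mcnemar_test(y, pa, pb)
        assert not res["exact"]
        assert res["statistic"] == pytest.approx(1.0 / 30.0)


class TestIouDice:
    def test_identical_masks(self):
        m = np.array([[1, 1], [0, 2]])
        out = iou_dice(m, m)
        assert out[1]["iou"] == 1.0 and out[1]["dice"] == 1.0
        assert out[2]["iou"] == 1.0
        assert np.isnan(out[3]["iou"])  # absent from both

    def test_disjoint_masks(self):
        p = np.array([[1, 0], [0, 0]])
        t = np.array([[0, 1], [0, 0]])
        out = iou_dice(p, t)
        assert out[1]["iou"] == 0.0 and out[1]["dice"] == 0.0

    def test_partial_overlap_hand_values(self):
        p = np.array([[1, 1, 0]])
        t = np.array([[0, 1, 1]])
        out = iou_dice(p, t)
        assert out[1]["iou"] == pytest.approx(1 / 3)
        assert out[1]["dice"] == pytest.approx(0.5)

    def test_dice_iou_identity(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            p = rng.integers(0, 5, size=(12, 12))
            t = rng.integers(0, 5, size=(12, 12))
            for stats in iou_dice(p, t).values():
                if not np.isnan(stats["iou"]):
                    expected = 2 * stats["iou"] / (1 + stats["iou"])
                    assert stats["dice"] == pytest.approx(expected, abs=1e-12)


class TestArteryDetection:
    def test_perfect_agreement(self):
        masks = [np.array([[1, 2], [3, 4]]), np.array([[0, 0], [0, 1]])]
        out = artery_detection_metrics(masks, masks)
        for name in ("RCA", "LAD", "LCA", "LCX"):
            assert out[name]["f1"] in (1.0, 1.0)

    def test_never_predicting_a_class(self):
        t = [np.array([[2]]), np.array([[2]])]
        p = [np.zeros((1, 1), dtype=int)] * 2
        out = artery_detection_metrics(p, t)
        assert out["LAD"]["recall"] == 0.0
        assert np.isnan(out["LAD"]["precision"])

    def test_four_patient_hand_tally(self):
        # RCA: pred present in 2 patients, truth in 3, overlap 2
        t = [np.array([[1]]), np.array([[1]]), np.array([[1]]), np.array([[0]])]
        p = [np.array([[1]]), np.array([[1]]), np.array([[0]]), np.array([[0]])]
        out = artery_detection_metrics(p, t)
        assert out["RCA"]["precision"] == 1.0
        assert out["RCA"]["recall"] == pytest.approx(2 / 3)


class TestRiskConfusion:
    def test_perfect_agreement_all_ones(self):
        risks = ["low", "moderate", "high", "very_high"] * 3
        out = risk_confusion(risks, risks)
        assert out["accuracy"] == 1.0
        assert np.array_equal(np.diag(out["matrix"]), [3, 3, 3, 3])
        for cat in out["per_category"].values():
            assert cat["f1"] == 1.0 and cat["specificity"] == 1.0

    def test_single_error_hand_computation(self):
        true = ["low"] * 5 + ["moderate"] * 5
        pred = ["low"] * 4 + ["moderate"] + ["moderate"] * 5
        out = risk_confusion(pred, true)
        assert out["accuracy"] == pytest.approx(0.9)
        assert out["per_category"]["low"]["recall"] == pytest.approx(0.8)
        assert out["per_category"]["moderate"]["precision"] == pytest.approx(5 / 6)

    def test_weighted_recall_equals_accuracy(self):
        rng = np.random.default_rng(1)
        cats = ["low", "moderate", "high", "very_high"]
        true = [cats[i] for i in rng.integers(0, 4, size=50)]
        pred = [cats[i] for i in rng.integers(0, 4, size=50)]
        out = risk_confusion(pred, true)
        assert out["weighted_avg"]["recall"] == pytest.approx(out["accuracy"])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            risk_confusion([], [])
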