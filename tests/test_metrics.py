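"""Evaluation metrics against brute-force enumeration and hand-worked values."""

import numpy as np
import pytest
from skimage import measure
from sklearn.metrics import average_precision_score

from cmbcascade import losses, metrics


class TestConfusion:
    def test_identical_masks_have_no_errors(self, rng):
        m = (rng.random((6, 6)) > 0.5).astype(np.uint8)
        c = metrics.confusion(m, m)
        assert c.fp == 0 and c.fn == 0 and c.n == 36

    def test_complement_has_no_agreement(self, rng):
        m = (rng.random((6, 6)) > 0.5).astype(np.uint8)
        c = metrics.confusion(1 - m, m)
        assert c.tp == 0 and c.tn == 0

    def test_hand_enumerated_2x2(self):
        pred = np.array([[1, 1], [0, 0]])
        truth = np.array([[1, 0], [1, 0]])
        c = metrics.confusion(pred, truth)
        assert (c.tp, c.tn, c.fp, c.fn) == (1, 1, 1, 1)

    def test_nonbinary_mask_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            metrics.confusion(np.array([[2]]), np.array([[1]]))


class TestPixelMetrics:
    def test_perfect_prediction_scores_one_everywhere(self):
        m = metrics.pixel_metrics(metrics.ConfusionCounts(5, 10, 0, 0))
        assert all(v == 1.0 for v in m.values())

    def test_hand_worked_counts(self):
        m = metrics.pixel_metrics(metrics.ConfusionCounts(2, 10, 1, 1))
        assert m["sen"] == pytest.approx(2 / 3)
        assert m["pre"] == pytest.approx(2 / 3)
        assert m["dsc"] == pytest.approx(2 / 3)
        assert m["jsc"] == pytest.approx(1 / 2)
        assert m["f2"] == pytest.approx(2 / 3)
        assert m["mcc"] == pytest.approx(19 / 33)

    def test_f2_equals_common_value_when_pre_equals_sen(self):
        # 5ps/(4p+s) = p when p == s
        m = metrics.pixel_metrics(metrics.ConfusionCounts(3, 5, 1, 1))
        assert m["pre"] == m["sen"] == pytest.approx(m["f2"])

    def test_both_empty_is_perfect(self):
        m = metrics.pixel_metrics(metrics.ConfusionCounts(0, 20, 0, 0))
        assert all(v == 1.0 for v in m.values())

    def test_total_miss_scores_zero(self):
        m = metrics.pixel_metrics(metrics.ConfusionCounts(0, 18, 0, 2))
        assert m["sen"] == 0.0 and m["dsc"] == 0.0 and m["pre"] == 0.0


def test_all_metrics_match_bruteforce_enumeration(random_mask_pairs):
    """Six metrics vs an independent per-pixel counting oracle, 1,000 pairs."""
    for pred, truth in random_mask_pairs:
        tp = tn = fp = fn = 0
        for p, t in zip(pred.ravel().tolist(), truth.ravel().tolist()):
            if p and t: tp += 1
            elif p and not t: fp += 1
            elif not p and t: fn += 1
            else: tn += 1
        got = metrics.pixel_metrics(metrics.confusion(pred, truth))
        if tp + fp + fn == 0:
            assert all(v == 1.0 for v in got.values())
            continue
        def safe(n, d):
            return n / d if d > 0 else 0.0
        sen = safe(tp, tp + fn); pre = safe(tp, tp + fp)
        mden = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
        want = {
            "sen": sen, "pre": pre,
            "dsc": safe(2 * tp, 2 * tp + fp + fn),
            "f2": safe(5 * pre * sen, 4 * pre + sen),
            "jsc": safe(tp, tp + fn + fp),
            "mcc": (tp * tn - fp * fn) / mden if mden > 0 else 0.0,
        }
        for k in want:
            assert got[k] == pytest.approx(want[k], abs=1e-12), k


def test_dsc_complements_unsmoothed_dice_loss(rng):
    """DSC(pred, truth) = 1 - dice_loss(pred, truth) on binary masks."""
    for _ in range(50):
        pred = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        truth = (rng.random((8, 8)) > 0.5).astype(np.uint8)
        if truth.sum() == 0 or pred.sum() + truth.sum() == 0:
            continue
        dsc = metrics.pixel_metrics(metrics.confusion(pred, truth))["dsc"]
        dl = losses.dice_loss(pred.astype(float), truth.astype(float)).item()
        assert dsc == pytest.approx(1 - dl, abs=1e-12)


def test_metric_symmetries(rng):
    for _ in range(30):
        a = (rng.random((7, 7)) > 0.5).astype(np.uint8)
        b = (rng.random((7, 7)) > 0.5).astype(np.uint8)
        mab = metrics.pixel_metrics(metrics.confusion(a, b))
        mba = metrics.pixel_metrics(metrics.confusion(b, a))
        assert mab["dsc"] == pytest.approx(mba["dsc"])
        assert mab["jsc"] == pytest.approx(mba["jsc"])
        assert mab["pre"] == pytest.approx(mba["sen"])


def test_f2_lies_between_pre_and_sen_and_leans_to_sen(rng):
    for _ in range(50):
        c = metrics.ConfusionCounts(*(int(x) for x in rng.integers(1, 30, 4)))
        m = metrics.pixel_metrics(c)
        lo, hi = sorted((m["pre"], m["sen"]))
        assert lo - 1e-12 <= m["f2"] <= hi + 1e-12
        if abs(m["pre"] - m["sen"]) > 1e-9:
            f1 = 2 * m["pre"] * m["sen"] / (m["pre"] + m["sen"])
            assert abs(m["f2"] - m["sen"]) < abs(f1 - m["sen"])


def test_mcc_sign_flips_under_prediction_complement():
    truth = np.kron(np.eye(2), np.ones((2, 2))).astype(np.uint8)  # balanced
    pred = truth.copy()
    m = metrics.pixel_metrics(metrics.confusion(pred, truth))["mcc"]
    mflip = metrics.pixel_metrics(metrics.confusion(1 - pred, truth))["mcc"]
    assert m == pytest.approx(1.0) and mflip == pytest.approx(-1.0)


class TestLesionDetection:
    def test_identical_components_all_matched(self):
        truth = np.zeros((10, 10), np.uint8)
        truth[1:3, 1:3] = 1; truth[5:7, 5:7] = 1; truth[8:10, 0:2] = 1
        d = metrics.lesion_detection_stats(truth, truth)
        assert d.matched_truth == 3 and d.false_positive_components == 0

    def test_one_hit_one_false_positive(self):
        truth = np.zeros((10, 10), np.uint8); truth[2:5, 2:5] = 1
        pred = np.zeros_like(truth)
        pred[3, 3] = 1          # overlaps truth
        pred[8, 8] = 1          # far away
        d = metrics.lesion_detection_stats(pred, truth)
        assert (d.matched_truth, d.false_positive_components) == (1, 1)
        assert metrics.fp_avg([pred], [truth]) == pytest.approx(1.0)

    def test_empty_prediction_misses_everything(self):
        truth = np.zeros((8, 8), np.uint8); truth[0, 0] = 1; truth[5, 5] = 1
        d = metrics.lesion_detection_stats(np.zeros_like(truth), truth)
        assert (d.matched_truth, d.missed_truth, d.false_positive_components) == (0, 2, 0)

    def test_component_counts_agree_with_skimage(self, rng):
        for _ in range(20):
            pred = (rng.random((12, 12)) > 0.7).astype(np.uint8)
            truth = (rng.random((12, 12)) > 0.7).astype(np.uint8)
            d = metrics.lesion_detection_stats(pred, truth)
            assert d.truth_components == measure.label(truth, connectivity=2).max()

    def test_min_iou_variant_is_stricter(self):
        truth = np.zeros((10, 10), np.uint8); truth[0:4, 0:4] = 1
        pred = np.zeros_like(truth); pred[3, 3] = 1  # 1/16 IoU
        loose = metrics.lesion_detection_stats(pred, truth)
        strict = metrics.lesion_detection_stats(pred, truth, min_iou=0.5)
        assert loose.matched_truth == 1 and strict.matched_truth == 0


class TestPrCurve:
    def test_perfect_ranking_gives_ap_one(self):
        truth = np.zeros((4, 4), np.uint8); truth[1:3, 1:3] = 1
        _, _, ap = metrics.pr_curve(truth.astype(float), truth)
        assert ap == pytest.approx(1.0)

    def test_constant_score_precision_is_prevalence(self):
        truth = np.zeros((4, 4), np.uint8); truth[0] = 1
        prec, rec, ap = metrics.pr_curve(np.full((4, 4), 0.5), truth)
        np.testing.assert_allclose(prec, 0.25)

    def test_ap_matches_exhaustive_threshold_enumeration(self, rng):
        """8-pixel toy map: AP from explicit threshold sweep."""
        for _ in range(20):
            scores = rng.random(8)
            truth = (rng.random(8) > 0.5).astype(np.uint8)
            if truth.sum() == 0:
                truth[0] = 1
            prob = scores.reshape(2, 4)
            tm = truth.reshape(2, 4)
            _, _, ap = metrics.pr_curve(prob, tm)
            # oracle: step-curve area over all distinct thresholds
            pts = []
            for t in sorted(set(scores), reverse=True):
                pred = scores >= t
                tp = int((pred & (truth == 1)).sum())
                pts.append((tp / truth.sum(), tp / pred.sum()))
            area, prev_r = 0.0, 0.0
            for r, p in pts:
                area += (r - prev_r) * p
                prev_r = r
            assert ap == pytest.approx(area, abs=1e-12)
            assert ap == pytest.approx(
                average_precision_score(truth, scores), abs=1e-9)

    def test_no_positive_truth_rejected(self):
        with pytest.raises(ValueError, match="no positive"):
            metrics.pr_curve(np.zeros((3, 3)), np.zeros((3, 3), np.uint8))


def test_evaluate_pairs_and_summarize(rng):
    preds, truths = [], []
    for _ in range(4):
        t = (rng.random((9, 9)) > 0.7).astype(np.uint8)
        preds.append(t); truths.append(t)
    tab = metrics.evaluate_pairs(preds, truths)
    assert len(tab) == 4
    s = metrics.summarize(tab)
    assert s["dsc_mean"] == pytest.approx(1.0)
    assert s["dsc_sd"] == pytest.approx(0.0)
    assert s["fp_avg"] == pytest.approx(0.0)
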