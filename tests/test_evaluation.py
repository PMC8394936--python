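"""Matching, one-vs-rest metrics, kappa, threshold curves, angle errors."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from ciliaquant.detection import Detection
from ciliaquant.evaluation import (BACKGROUND_LABEL, ConfusionCounts,
                                   angle_error_stats, classification_metrics,
                                   cohen_kappa, confusion_counts,
                                   confusion_matrix_from_matching,
                                   match_points, pr_f1_curves, round_half_up)


def P(x, y, cls="normal", score=None):
    return (x, y, cls) if score is None else Detection(
        box=(x - 50, y - 50, 100, 100), class_label=cls, score=score)


class TestMatchPoints:
    def test_close_pair_matches(self):
        m = match_points([P(100, 100)], [P(102, 101)], 30)
        assert len(m.pairs) == 1

    def test_distant_prediction_unmatched(self):
        m = match_points([P(0, 0)], [P(200, 0)], 55)
        assert m.pairs == [] and m.unmatched_pred == [0]
        assert m.unmatched_truth == [0]

    def test_closer_of_two_predictions_wins(self):
        m = match_points([P(110, 100), P(104, 100)], [P(100, 100)], 55)
        assert m.pairs[0][0] == 1  # the 4-px prediction
        assert m.unmatched_pred == [0]

    def test_greedy_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            preds = [P(*rng.uniform(0, 200, 2)) for _ in range(int(rng.integers(0, 7)))]
            truths = [P(*rng.uniform(0, 200, 2)) for _ in range(int(rng.integers(0, 7)))]
            radius = 60.0
            m = match_points(preds, truths, radius)
            # oracle: pick globally closest admissible pair, repeat
            d = {(i, j): math.dist(p[:2], t[:2])
                 for i, p in enumerate(preds) for j, t in enumerate(truths)}
            expect, up, ut = [], set(range(len(preds))), set(range(len(truths)))
            for (i, j), dist in sorted(d.items(), key=lambda kv: (kv[1], kv[0])):
                if dist <= radius and i in up and j in ut:
                    expect.append((i, j))
                    up.discard(i)
                    ut.discard(j)
            assert [(i, j) for i, j, _ in m.pairs] == sorted(
                expect, key=lambda ij: d[ij])

    def test_infinite_radius_pairs_everything(self):
        rng = np.random.default_rng(5)
        preds = [P(*rng.uniform(0, 500, 2)) for _ in range(8)]
        truths = [P(*rng.uniform(0, 500, 2)) for _ in range(8)]
        m = match_points(preds, truths, math.inf)
        assert len(m.pairs) == 8

    def test_negative_radius_rejected(self):
        with pytest.raises(ValueError):
            match_points([], [], -1)


class TestConfusionCounts:
    def test_perfect_predictions(self):
        pts = [P(50 * i, 50 * i, c) for i, c in
               enumerate(["normal"] * 6 + ["primary", "secondary"] * 2)]
        cc = confusion_counts(match_points(pts, pts, 10))
        for c in ("normal", "primary", "secondary"):
            assert cc.per_class[c]["fp"] == 0 and cc.per_class[c]["fn"] == 0

    def test_single_label_swap(self):
        truth = [P(100, 100, "normal")]
        pred = [P(101, 100, "secondary")]
        cc = confusion_counts(match_points(pred, truth, 30))
        assert cc.per_class["secondary"]["fp"] == 1
        assert cc.per_class["normal"]["fn"] == 1
        assert cc.per_class["primary"]["tn"] == 1

    def test_counts_equal_hand_enumeration(self):
        # 3 matched (normal/normal, primary->secondary, secondary/secondary),
        # 1 unmatched prediction (primary), 1 unmatched annotation (normal)
        truth = [P(0, 0, "normal"), P(200, 0, "primary"),
                 P(400, 0, "secondary"), P(600, 0, "normal")]
        pred = [P(1, 0, "normal"), P(201, 0, "secondary"),
                P(401, 0, "secondary"), P(900, 0, "primary")]
        cc = confusion_counts(match_points(pred, truth, 30))
        # events: (n,n) (p,s) (s,s) (bg,p) (n,bg)  -> 5 events per class
        assert cc.per_class["normal"] == {"tp": 1, "fp": 0, "tn": 3, "fn": 1}
        assert cc.per_class["primary"] == {"tp": 0, "fp": 1, "tn": 3, "fn": 1}
        assert cc.per_class["secondary"] == {"tp": 1, "fp": 1, "tn": 3, "fn": 0}
        assert cc.overall["tp"] == 2


class TestClassificationMetrics:
    def test_all_correct_gives_hundred_percent(self):
        cc = ConfusionCounts(per_class={
            c: {"tp": 5, "fp": 0, "tn": 10, "fn": 0}
            for c in ("normal", "primary", "secondary")})
        rep = classification_metrics(cc)
        assert (rep.table.loc["overall"] == 100.0).all()

    def test_zero_denominator_marks_undefined(self):
        cc = ConfusionCounts(per_class={
            "normal": {"tp": 0, "fp": 0, "tn": 5, "fn": 0},
            "primary": {"tp": 1, "fp": 1, "tn": 1, "fn": 1},
            "secondary": {"tp": 1, "fp": 1, "tn": 1, "fn": 1}})
        rep = classification_metrics(cc)
        assert math.isnan(rep["normal"]["precision"])
        assert math.isnan(rep["normal"]["sensitivity"])
        assert rep["normal"]["accuracy"] == 100.0

    def test_rounding_is_half_up(self):
        assert round_half_up(80.725) == 80.73
        assert round_half_up(43.373) == 43.37
        assert round_half_up(0.005) == 0.01


class TestCohenKappa:
    def test_diagonal_matrix_is_perfect_agreement(self):
        assert cohen_kappa(np.diag([5, 9, 2, 7])) == pytest.approx(1.0)

    def test_chance_level_agreement_is_zero(self):
        assert cohen_kappa(np.array([[25, 25], [25, 25]])) == pytest.approx(0.0)

    def test_hand_computed_three_by_three(self):
        m = np.array([[20, 5, 0], [3, 15, 2], [1, 4, 10]])
        # by hand: N=60, po=45/60=0.75; pe=(25*24+20*24+15*12)/3600=0.35
        # kappa = (0.75-0.35)/(1-0.35) = 8/13
        assert cohen_kappa(m) == pytest.approx(8.0 / 13.0)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(6)
        m = rng.integers(0, 20, (4, 4))
        k = cohen_kappa(m)
        perm = rng.permutation(4)
        assert cohen_kappa(m[np.ix_(perm, perm)]) == pytest.approx(k)

    def test_off_diagonal_mass_reduces_kappa(self):
        base = np.diag([10, 10, 10]).astype(float)
        noisy = base.copy()
        noisy[0, 1] += 5
        assert cohen_kappa(noisy) < cohen_kappa(base)

    def test_background_exclusion_drops_label(self):
        labels = ["normal", "primary", "secondary", BACKGROUND_LABEL]
        m = pd.DataFrame(np.diag([5, 5, 5, 0]) + 1, index=labels,
                         columns=labels)
        with_bg = cohen_kappa(m, include_background=True)
        without = cohen_kappa(m, include_background=False)
        assert with_bg != without
        # excluding background must equal kappa of the 3x3 upper block
        assert without == pytest.approx(
            cohen_kappa(m.iloc[:3, :3].to_numpy()))

    def test_degenerate_single_label_is_nan(self):
        m = np.zeros((3, 3))
        m[0, 0] = 10
        assert math.isnan(cohen_kappa(m))


class TestPrF1Curves:
    def test_perfect_scorer_is_flat_at_one(self):
        truth = [P(i * 200, 0, c) for i, c in
                 enumerate(["normal", "primary", "secondary"])]
        preds = [P(i * 200, 1, c, score=1.0) for i, c in
                 enumerate(["normal", "primary", "secondary"])]
        curve, best = pr_f1_curves(preds, truth, 55)
        assert np.allclose(curve["precision"], 1.0)
        assert np.allclose(curve["recall"], 1.0)
        assert np.allclose(curve["f1"], 1.0)

    def test_threshold_above_all_scores_zeroes_recall(self):
        truth = [P(0, 0, "normal")]
        preds = [P(0, 1, "normal", score=0.4)]
        curve, _ = pr_f1_curves(preds, truth, 55, thresholds=[0.9])
        assert curve["recall"].iloc[0] == 0.0

    def test_curve_equals_bruteforce_recomputation(self):
        rng = np.random.default_rng(13)
        classes = ["normal", "primary", "secondary"]
        truth = [P(float(x), float(y), classes[i % 3])
                 for i, (x, y) in enumerate(rng.uniform(0, 900, (10, 2)))]
        # two deliberate mis-scorings: wrong class, and a spurious point
        preds = [P(t[0] + 3, t[1], t[2], score=float(rng.uniform(0.3, 1)))
                 for t in truth[:8]]
        preds.append(P(truth[8][0], truth[8][1], "secondary", score=0.95))
        preds.append(P(950.0, 950.0, "primary", score=0.6))
        thresholds = [0.0, 0.25, 0.5, 0.75, 1.0]
        curve, _ = pr_f1_curves(preds, truth, 55, thresholds=thresholds)
        for row in curve.itertuples():
            kept = [p for p in preds if p.score >= row.threshold]
            cc = confusion_counts(match_points(kept, truth, 55))
            precs = [cc.per_class[c]["tp"] / (cc.per_class[c]["tp"] + cc.per_class[c]["fp"])
                     for c in classes
                     if cc.per_class[c]["tp"] + cc.per_class[c]["fp"] > 0]
            recs = [cc.per_class[c]["tp"] / (cc.per_class[c]["tp"] + cc.per_class[c]["fn"])
                    for c in classes
                    if cc.per_class[c]["tp"] + cc.per_class[c]["fn"] > 0]
            p = np.mean(precs) if precs else 0.0
            r = np.mean(recs) if recs else 0.0
            assert row.precision == pytest.approx(p)
            assert row.recall == pytest.approx(r)
            f1 = 2 * p * r / (p + r) if p + r else 0.0
            assert row.f1 == pytest.approx(f1)

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            pr_f1_curves([], [], 55)


class TestAngleErrorStats:
    def test_identical_angles(self):
        s = angle_error_stats([10.0, 50.0, 90.0], [10.0, 50.0, 90.0])
        assert s.mae_deg == 0.0
        assert s.pct_within_5deg == 100.0
        assert s.wilcoxon_p == 1.0

    def test_constant_offset(self):
        pred = [20.0, 40.0, 60.0, 80.0]
        corr = [10.0, 30.0, 50.0, 70.0]
        s = angle_error_stats(pred, corr)
        assert s.mae_deg == pytest.approx(10.0)
        assert s.pct_within_5deg == 0.0

    def test_axial_error_definition(self):
        s = angle_error_stats([0.0, 90.0], [170.0, 80.0])
        assert s.mae_deg == pytest.approx(10.0)

    def test_sentinels_excluded_pairwise(self):
        s = angle_error_stats([10.0, -1.0, 30.0], [12.0, 40.0, -1.0])
        assert s.n_pairs == 1
        assert s.mae_deg == pytest.approx(2.0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            angle_error_stats([1.0], [1.0, 2.0])

    def test_confusion_matrix_from_matching_totals(self):
        truth = [P(0, 0, "normal"), P(300, 0, "primary")]
        pred = [P(1, 0, "normal"), P(600, 0, "secondary")]
        m = confusion_matrix_from_matching(match_points(pred, truth, 30))
        assert m.to_numpy().sum() == 3  # 1 match + 1 spurious + 1 missed
        assert m.loc["normal", "normal"] == 1
        assert m.loc[BACKGROUND_LABEL, "secondary"] == 1
        assert m.loc["primary", BACKGROUND_LABEL] == 1
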