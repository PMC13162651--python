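"""Metrics against hand formulas and brute-force ranking oracles."""

import itertools
import math

import numpy as np
import pytest

from ovosex.evaluation import (ConfusionCounts, ScoredPredictions,
                               activation_ratio, classification_metrics,
                               pr_ap, roc_auc, subset_report)


def pairwise_concordance(y, s):
    """AUC oracle: P(score_pos > score_neg), ties counted one half."""
    pos = [si for yi, si in zip(y, s) if yi == 1]
    neg = [si for yi, si in zip(y, s) if yi == 0]
    total = hits = 0
    for p, n in itertools.product(pos, neg):
        total += 1
        hits += 1.0 if p > n else (0.5 if p == n else 0.0)
    return hits / total


def step_ap_oracle(y, s):
    """AP oracle: sum over recall steps of precision at each threshold."""
    order = np.argsort(-np.asarray(s), kind="stable")
    y = np.asarray(y)[order]
    n_pos = y.sum()
    ap = 0.0
    tp = fp = 0
    prev_recall = 0.0
    for i in range(len(y)):
        if y[i] == 1:
            tp += 1
        else:
            fp += 1
        # only evaluate at distinct-score boundaries
        if i + 1 < len(y) and s[order[i]] == s[order[i + 1]]:
            continue
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


class TestClassificationMetrics:
    def test_perfect_predictions(self):
        m = classification_metrics(ConfusionCounts(tp=10, fp=0, fn=0, tn=10))
        assert (m["accuracy"], m["precision"], m["recall"], m["f1"],
                m["kappa"]) == (1, 1, 1, 1, 1)

    def test_all_female_predictions_on_balanced_set(self):
        m = classification_metrics(ConfusionCounts(tp=50, fp=50, fn=0, tn=0))
        assert m["accuracy"] == pytest.approx(0.5)
        assert m["kappa"] == pytest.approx(0.0)

    def test_worked_table_against_hand_formula(self):
        c = ConfusionCounts(tp=45, fn=5, fp=10, tn=40)
        m = classification_metrics(c)
        assert m["accuracy"] == pytest.approx(0.85)
        po = 0.85
        pe = (55 / 100) * (50 / 100) + (45 / 100) * (50 / 100)
        assert m["kappa"] == pytest.approx((po - pe) / (1 - pe))
        assert m["precision"] == pytest.approx(45 / 55)
        assert m["recall"] == pytest.approx(45 / 50)

    def test_zero_denominators_flagged_not_zeroed(self):
        m = classification_metrics(ConfusionCounts(tp=0, fp=0, fn=5, tn=5))
        assert m["precision"] is None
        assert "precision" in m["undefined"]

    def test_kappa_null_under_marginal_preserving_shuffles(self):
        """Kappa concentrates on 0 when predictions are independent of
        labels: mean |kappa| < 0.05 over 100 seeded shuffles."""
        rng = np.random.default_rng(0)
        y = np.array([1] * 60 + [0] * 40)
        pred = np.array([1] * 55 + [0] * 45)
        kappas = []
        for _ in range(100):
            p = rng.permutation(pred)
            c = ConfusionCounts.from_predictions(y, p)
            kappas.append(classification_metrics(c)["kappa"])
        assert abs(np.mean(kappas)) < 0.05

    def test_order_invariance(self, rng):
        y = rng.integers(0, 2, 30)
        p = rng.integers(0, 2, 30)
        perm = rng.permutation(30)
        a = classification_metrics(ConfusionCounts.from_predictions(y, p))
        b = classification_metrics(ConfusionCounts.from_predictions(y[perm], p[perm]))
        assert a == b


class TestROC:
    def test_perfect_separation(self):
        preds = ScoredPredictions(y_true=[1, 1, 0, 0], y_pred=[1, 1, 0, 0],
                                  score=[0.9, 0.8, 0.2, 0.1])
        assert roc_auc(preds)["auc"] == pytest.approx(1.0)

    def test_small_case_matches_exhaustive_pair_count(self):
        y, s = [1, 0, 1, 0], [0.9, 0.8, 0.4, 0.3]
        preds = ScoredPredictions(y_true=y, y_pred=y, score=s)
        assert roc_auc(preds)["auc"] == pytest.approx(pairwise_concordance(y, s))

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(5)
        y = np.array([0, 1] * 1000)
        s = rng.uniform(size=2000)
        preds = ScoredPredictions(y_true=y, y_pred=(s > 0.5).astype(int), score=s)
        assert abs(roc_auc(preds)["auc"] - 0.5) < 0.05

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc(ScoredPredictions(y_true=[1, 1], y_pred=[1, 1],
                                      score=[0.5, 0.6]))

    @pytest.mark.parametrize("trial", range(20))
    def test_auc_equals_concordance_with_ties(self, trial):
        rng = np.random.default_rng(trial)
        n = int(rng.integers(6, 50))
        y = rng.integers(0, 2, n)
        if len(np.unique(y)) < 2:
            y[0], y[1] = 0, 1
        s = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)   # induces ties
        preds = ScoredPredictions(y_true=y, y_pred=(s > 0.5).astype(int), score=s)
        assert roc_auc(preds)["auc"] == pytest.approx(
            pairwise_concordance(y, s), abs=1e-9)


class TestPR:
    def test_perfect_ranking(self):
        preds = ScoredPredictions(y_true=[1, 1, 0, 0], y_pred=[1, 1, 0, 0],
                                  score=[0.9, 0.8, 0.2, 0.1])
        assert pr_ap(preds)["ap"] == pytest.approx(1.0)

    def test_constant_scores_give_prevalence(self):
        y = [1, 1, 0, 0, 0]
        preds = ScoredPredictions(y_true=y, y_pred=[1] * 5, score=[0.5] * 5)
        assert pr_ap(preds)["ap"] == pytest.approx(0.4)

    def test_six_sample_case_matches_step_integration_oracle(self):
        y = [1, 0, 1, 1, 0, 0]
        s = [0.95, 0.85, 0.75, 0.55, 0.45, 0.15]
        preds = ScoredPredictions(y_true=y, y_pred=[1, 1, 1, 0, 0, 0], score=s)
        assert pr_ap(preds)["ap"] == pytest.approx(step_ap_oracle(y, s), abs=1e-9)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            pr_ap(ScoredPredictions(y_true=[0, 0], y_pred=[0, 0],
                                    score=[0.2, 0.3]))


class TestSubsets:
    def test_single_stratum_equals_overall(self):
        preds = ScoredPredictions(y_true=[1, 0, 1], y_pred=[1, 0, 0],
                                  score=[0.9, 0.2, 0.3],
                                  quality=["normal"] * 3)
        rep = subset_report(preds)
        assert rep["strata"]["normal"]["accuracy"] == rep["overall"]["accuracy"]

    def test_stratum_accuracies_recombine_by_count_weighting(self, rng):
        n = 200
        quality = rng.choice(["normal", "blurry", "bubble"], size=n)
        y = rng.integers(0, 2, n)
        p = rng.integers(0, 2, n)
        rep = subset_report(ScoredPredictions(
            y_true=y, y_pred=p, score=np.full(n, 0.5), quality=quality))
        weighted = sum(r["n"] * r["accuracy"] for r in rep["strata"].values())
        assert weighted / n == pytest.approx(rep["overall"]["accuracy"])

    def test_paper_strata_counts_echoed(self):
        quality = np.repeat(["normal", "low-or-over-exposed", "bubble", "blurry"],
                            [420, 120, 130, 100])
        n = len(quality)
        rep = subset_report(ScoredPredictions(
            y_true=np.zeros(n, int), y_pred=np.zeros(n, int),
            score=np.full(n, 0.5), quality=quality))
        assert rep["strata"]["normal"]["n"] == 420
        assert rep["strata"]["low-or-over-exposed"]["n"] == 120
        assert rep["strata"]["bubble"]["n"] == 130
        assert rep["strata"]["blurry"]["n"] == 100


class TestActivationRatio:
    def test_uniform_heatmap_gives_unit_ratio(self):
        heat = np.ones((10, 10))
        mask = np.zeros((10, 10), bool)
        mask[4:6, 4:6] = True
        assert activation_ratio(heat, mask)["ratio"] == pytest.approx(1.0)

    def test_heatmap_equal_to_mask_flags_infinite(self):
        mask = np.zeros((8, 8), bool)
        mask[2, 2] = True
        out = activation_ratio(mask.astype(float), mask)
        assert math.isinf(out["ratio"]) and out["flag"] == "infinite"

    def test_matches_direct_mean_oracle(self, rng):
        heat = rng.uniform(size=(12, 12))
        mask = rng.uniform(size=(12, 12)) > 0.7
        egg = rng.uniform(size=(12, 12)) > 0.1
        mask &= egg
        if not mask.any():
            mask[3, 3] = True
        out = activation_ratio(heat, mask, egg_mask=egg)
        v = np.mean([heat[i, j] for i, j in zip(*np.where(mask))])
        b = np.mean([heat[i, j] for i, j in zip(*np.where(egg & ~mask))])
        assert out["ratio"] == pytest.approx(v / b, abs=1e-9)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            activation_ratio(np.ones((4, 4)), np.zeros((4, 4), bool))
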