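import numpy as np
import pytest
from scipy.special import expit
from scipy.stats import chi2

from binsurv import (
    RiskOutput,
    TimeBinning,
    auc_3yr,
    concordance_index,
    confusion_at_threshold,
    evaluate_predictions,
    km_logrank,
    predicted_duration,
    roc_threshold,
)


def brute_force_cindex(pred, obs, events):
    """Independent O(n^2) pair enumeration of Harrell's C."""
    num = den = 0.0
    n = len(obs)
    for i in range(n):
        for k in range(n):
            if obs[i] < obs[k] and events[i]:
                den += 1
                if pred[i] < pred[k]:
                    num += 1
                elif pred[i] == pred[k]:
                    num += 0.5
    return num / den


class TestPredictedDuration:
    def test_point_mass_returns_that_midpoint(self):
        binning = TimeBinning(np.arange(0.0, 11.0))
        scores = np.full((1, 10), -100.0)
        scores[0, 5] = 100.0  # softmax puts all mass on bin 6, midpoint 5.5
        out = RiskOutput(scores, "risk", binning)
        assert predicted_duration(out)[0] == pytest.approx(5.5)

    def test_uniform_weights_give_half_range(self):
        binning = TimeBinning(np.arange(0.0, 9.0))
        out = RiskOutput(np.zeros((1, 8)), "risk", binning)
        assert predicted_duration(out)[0] == pytest.approx(binning.t_end / 2)

    def test_survival_step_drop_lands_on_drop_bin_midpoint(self):
        binning = TimeBinning(np.arange(0.0, 5.0))
        survival = np.array([[1.0, 1.0, 0.0, 0.0]])  # drops entering bin 3
        out = RiskOutput(survival, "survival", binning)
        assert predicted_duration(out)[0] == pytest.approx(2.5)

    def test_remaining_mass_goes_to_last_bin(self):
        binning = TimeBinning(np.arange(0.0, 5.0))
        survival = np.array([[1.0, 1.0, 1.0, 1.0]])  # no drop anywhere
        out = RiskOutput(survival, "survival", binning)
        assert predicted_duration(out)[0] == pytest.approx(3.5)  # last midpoint

    def test_duration_bounded_by_binning_range(self):
        rng = np.random.default_rng(0)
        binning = TimeBinning(np.arange(0.0, 13.0))
        out = RiskOutput(rng.standard_normal((40, 12)), "risk", binning)
        durations = predicted_duration(out)
        assert np.all((durations >= 0) & (durations <= binning.t_end))


class TestConcordance:
    def test_perfect_predictions_score_one(self):
        obs = np.array([1.0, 3.0, 5.0, 9.0])
        assert concordance_index(obs, obs, np.ones(4, bool)) == 1.0

    def test_constant_predictions_score_half(self):
        obs = np.array([1.0, 3.0, 5.0])
        assert concordance_index(np.ones(3), obs, np.ones(3, bool)) == 0.5

    def test_matches_brute_force_on_random_censored_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(5, 120))
            obs = rng.exponential(10.0, n).round(1)  # rounding creates ties
            pred = rng.exponential(10.0, n).round(1)
            events = rng.random(n) < 0.5
            if not events.any() or not (obs[events][:, None] < obs[None, :]).any():
                continue
            assert concordance_index(pred, obs, events) == pytest.approx(
                brute_force_cindex(pred, obs, events)
            )

    def test_no_comparable_pairs_rejected(self):
        with pytest.raises(ValueError):
            concordance_index(np.array([1.0, 2.0]), np.array([3.0, 4.0]),
                              np.array([False, False]))

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        obs = rng.exponential(10.0, 60)
        pred = rng.exponential(10.0, 60)
        events = rng.random(60) < 0.4
        base = concordance_index(pred, obs, events)
        assert concordance_index(np.exp(pred / 10), obs, events) == pytest.approx(base)


class TestAuc3yr:
    def test_perfectly_ordered_predictions_score_one(self):
        obs = np.array([10.0, 20.0, 50.0, 55.0])
        events = np.array([True, True, False, False])
        pred = np.array([5.0, 8.0, 50.0, 60.0])
        auc, n_used = auc_3yr(pred, obs, events)
        assert auc == 1.0 and n_used == 4

    def test_censored_before_horizon_excluded(self):
        obs = np.array([10.0, 20.0, 30.0, 50.0])
        events = np.array([True, False, False, False])
        pred = np.array([5.0, 30.0, 30.0, 60.0])
        _, n_used = auc_3yr(pred, obs, events)
        assert n_used == 2  # two subjects censored before 36 months dropped

    def test_sigmoid_monotonicity_equals_negated_duration_auc(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(9)
        obs = rng.uniform(0, 80, 100)
        events = rng.random(100) < 0.5
        pred = rng.uniform(0, 80, 100)
        auc, _ = auc_3yr(pred, obs, events)
        keep = events | (obs >= 36.0)
        labels = (events & (obs <= 36.0))[keep].astype(int)
        assert auc == pytest.approx(roc_auc_score(labels, -pred[keep]))

    def test_label_flip_symmetry(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(10)
        events = rng.random(50) < 0.5
        obs = np.where(events, 10.0, 60.0)  # events early, censored late
        pred = rng.uniform(0, 80, 50)
        auc, _ = auc_3yr(pred, obs, events)
        keep = events | (obs >= 36.0)
        labels = (events & (obs <= 36.0))[keep].astype(int)
        assert roc_auc_score(1 - labels, expit(36.0 - pred[keep])) == pytest.approx(1.0 - auc)

    def test_single_class_after_exclusion_rejected(self):
        obs = np.array([10.0, 20.0])
        events = np.array([True, True])
        with pytest.raises(ValueError):
            auc_3yr(np.array([1.0, 2.0]), obs, events)

    def test_random_scores_near_half_at_large_n(self):
        rng = np.random.default_rng(11)
        n = 4000
        obs = np.where(rng.random(n) < 0.5, 10.0, 60.0)
        events = obs < 36
        pred = rng.uniform(0, 80, n)
        auc, _ = auc_3yr(pred, obs, events)
        assert abs(auc - 0.5) < 0.03


class TestRocThreshold:
    def test_perfect_separation_gives_tpr1_fpr0(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        threshold = roc_threshold(scores, labels)
        sens, spec, _ = confusion_at_threshold(scores, labels.astype(bool), threshold)
        assert (sens, spec) == (1.0, 1.0)

    def test_maximises_youden_over_exhaustive_candidates(self):
        scores = np.array([0.1, 0.3, 0.35, 0.6, 0.7, 0.9])
        labels = np.array([0, 1, 0, 1, 0, 1])
        threshold = roc_threshold(scores, labels)

        def youden(th):
            positive = scores >= th
            tpr = (positive & (labels == 1)).sum() / (labels == 1).sum()
            fpr = (positive & (labels == 0)).sum() / (labels == 0).sum()
            return tpr - fpr

        best = max(youden(th) for th in np.r_[scores, scores.max() + 1])
        assert youden(threshold) == pytest.approx(best)

    def test_two_point_threshold_separates_the_pair(self):
        threshold = roc_threshold(np.array([0.2, 0.8]), np.array([0, 1]))
        assert 0.2 < threshold <= 0.8

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_threshold(np.array([0.1, 0.2]), np.array([1, 1]))


class TestConfusion:
    def test_perfect_classifier(self):
        labels = np.array([True, True, False, False])
        scores = np.array([0.9, 0.8, 0.1, 0.2])
        assert confusion_at_threshold(scores, labels, 0.5) == (1.0, 1.0, 1.0)

    def test_all_positive_predictions(self):
        labels = np.array([True, False, False])
        sens, spec, _ = confusion_at_threshold(np.ones(3), labels, 0.5)
        assert (sens, spec) == (1.0, 0.0)

    def test_hand_built_two_by_two(self):
        # TP=3, FN=1, FP=2, TN=4 at threshold 0.6
        labels = np.array([1, 1, 1, 1, 0, 0, 0, 0, 0, 0], dtype=bool)
        scores = np.array([0.9, 0.8, 0.7, 0.2, 0.9, 0.6, 0.3, 0.2, 0.1, 0.0])
        sens, spec, acc = confusion_at_threshold(scores, labels, 0.6)
        assert sens == pytest.approx(0.75)
        assert spec == pytest.approx(2 / 3)
        assert acc == pytest.approx(0.7)


class TestKmLogrank:
    def test_identical_groups_have_null_statistic(self):
        obs = np.array([2.0, 5.0, 8.0, 2.0, 5.0, 8.0])
        events = np.array([True, True, False, True, True, False])
        groups = np.array(["a", "a", "a", "b", "b", "b"])
        _, p = km_logrank(groups, obs, events)
        assert p == pytest.approx(1.0)

    def test_matches_hand_computed_logrank_statistic(self):
        """Six subjects, all events, two disjoint groups; O-E and V by hand."""
        obs = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        events = np.ones(6, bool)
        groups = np.array(["early"] * 3 + ["late"] * 3)
        # hypergeometric accumulation over the six distinct event times
        observed = expected = variance = 0.0
        for t in np.unique(obs):
            at_risk = obs >= t
            d = float((obs == t).sum())
            n = float(at_risk.sum())
            n1 = float((at_risk & (groups == "early")).sum())
            observed += float(((obs == t) & (groups == "early")).sum())
            expected += d * n1 / n
            if n > 1:
                variance += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        statistic = (observed - expected) ** 2 / variance
        p_hand = float(chi2.sf(statistic, 1))
        _, p = km_logrank(groups, obs, events)
        assert p == pytest.approx(p_hand, rel=1e-6)

    def test_no_events_gives_flat_curves(self):
        obs = np.array([2.0, 3.0, 4.0, 5.0])
        events = np.zeros(4, bool)
        groups = np.array(["a", "a", "b", "b"])
        curves, p = km_logrank(groups, obs, events)
        assert np.all(curves["a"]["survival"] == 1.0)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            km_logrank(np.array(["a", "a"]), np.array([1.0, 2.0]),
                       np.array([True, False]))


def test_full_report_on_separable_cohort():
    rng = np.random.default_rng(21)
    n = 120
    risk = rng.random(n) < 0.5
    obs = np.where(risk, rng.uniform(5, 30, n), rng.uniform(40, 60, n))
    events = risk.copy()
    pred = obs + rng.normal(0, 2.0, n)
    report = evaluate_predictions(pred, obs, events)
    assert report.c_index > 0.9
    assert report.auc_3yr > 0.9
    assert report.logrank_p < 0.01
    assert report.n_excluded_for_auc == 0
    payload = report.to_json()
    assert "c_index" in payload
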