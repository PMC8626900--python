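import dataclasses

import numpy as np
import pytest

from fogait import FogEpisode
from fogait.evaluation import (
    ConfusionCounts,
    aggregate,
    confusion,
    detection_latency,
    evaluate_active_only,
    lopo_cv,
    metrics,
    non_freezer_validation,
    percent_time_frozen,
    state_breakdown,
)
from fogait.model import ModelConfig
from fogait.trial_store import STATE_STANDING, STATE_TURNING, STATE_WALKING


class TestConfusion:
    def test_perfect_prediction(self, rng):
        truth = rng.integers(0, 2, 200).astype(bool)
        c = confusion(truth, truth)
        assert c.fp == c.fn == 0
        assert c.tp == truth.sum() and c.tn == (~truth).sum()

    def test_inverted_prediction(self, rng):
        truth = rng.integers(0, 2, 200).astype(bool)
        c = confusion(~truth, truth)
        assert c.tp == c.tn == 0

    def test_matches_brute_force_loop(self, rng):
        pred = rng.integers(0, 2, 1000).astype(bool)
        truth = rng.integers(0, 2, 1000).astype(bool)
        c = confusion(pred, truth)
        tp = sum(1 for p, t in zip(pred, truth) if p and t)
        tn = sum(1 for p, t in zip(pred, truth) if not p and not t)
        fp = sum(1 for p, t in zip(pred, truth) if p and not t)
        fn = sum(1 for p, t in zip(pred, truth) if not p and t)
        assert (c.tp, c.tn, c.fp, c.fn) == (tp, tn, fp, fn)
        assert c.total == 1000

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.zeros(5), np.zeros(6))


class TestMetrics:
    def test_undefined_metrics_flagged(self):
        m = metrics(ConfusionCounts(tp=0, tn=10, fp=0, fn=0))
        assert m["sensitivity_pct"] is None
        assert m["precision_pct"] is None
        assert m["specificity_pct"] == 100.0

    def test_all_metrics_from_counts(self):
        m = metrics(ConfusionCounts(tp=80, tn=60, fp=40, fn=20))
        assert m["sensitivity_pct"] == pytest.approx(80.0)
        assert m["specificity_pct"] == pytest.approx(60.0)
        assert m["precision_pct"] == pytest.approx(80 / 120 * 100)
        sens, prec = 0.8, 80 / 120
        assert m["f1"] == pytest.approx(2 * sens * prec / (sens + prec))


class TestPercentTimeFrozen:
    def test_perfect_classifier_model_equals_true(self):
        m, t = percent_time_frozen(ConfusionCounts(tp=50, tn=150, fp=0, fn=0))
        assert m == t == pytest.approx(25.0)

    def test_true_value_is_label_prevalence(self, rng):
        pred = rng.integers(0, 2, 500).astype(bool)
        truth = rng.integers(0, 2, 500).astype(bool)
        _, true_pct = percent_time_frozen(confusion(pred, truth))
        assert true_pct == pytest.approx(100.0 * truth.mean())

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            percent_time_frozen(ConfusionCounts())


class TestDetectionLatency:
    TS = np.arange(1000) * 0.01

    def ep(self, onset, end):
        return FogEpisode(onset, end, "t")

    def run_pred(self, *ranges):
        pred = np.zeros(1000, dtype=bool)
        for a, b in ranges:
            pred[a:b] = True
        return pred

    def test_exact_match_zero_latency(self):
        out = detection_latency(
            self.run_pred((300, 500)), [self.ep(3.0, 5.0)], self.TS
        )
        assert out[0]["detected"] and out[0]["latency_s"] == pytest.approx(0.0)

    def test_missed_episode(self):
        out = detection_latency(
            self.run_pred((600, 650)), [self.ep(3.0, 5.0)], self.TS
        )
        assert not out[0]["detected"] and out[0]["latency_s"] is None

    def test_anticipating_run_negative_latency(self):
        out = detection_latency(
            self.run_pred((270, 400)), [self.ep(3.0, 5.0)], self.TS
        )
        assert out[0]["latency_s"] == pytest.approx(-0.30)

    def test_late_run_positive_latency(self):
        out = detection_latency(
            self.run_pred((350, 480)), [self.ep(3.0, 5.0)], self.TS
        )
        assert out[0]["latency_s"] == pytest.approx(0.50)

    def test_earliest_run_used_when_multiple(self):
        out = detection_latency(
            self.run_pred((320, 340), (400, 450)), [self.ep(3.0, 5.0)], self.TS
        )
        assert out[0]["latency_s"] == pytest.approx(0.20)

    def test_run_spanning_two_episodes_credits_first(self):
        eps = [self.ep(2.0, 3.0), self.ep(4.0, 5.0)]
        out = detection_latency(self.run_pred((150, 450)), eps, self.TS)
        assert out[0]["latency_s"] == pytest.approx(-0.50)
        # second episode detected by the same run; measured in-window
        assert out[1]["detected"]
        assert out[1]["latency_s"] == pytest.approx(0.0)

    def test_latency_below_episode_duration(self, rng):
        for _ in range(50):
            pred = rng.random(1000) < 0.3
            eps = [self.ep(2.0, 4.5)]
            out = detection_latency(pred, eps, self.TS)
            if out[0]["detected"]:
                assert out[0]["latency_s"] < 2.5


class TestStateBreakdown:
    def test_all_fp_in_walking(self):
        pred = np.array([1, 1, 0, 0], dtype=bool)
        truth = np.zeros(4, dtype=bool)
        states = np.array([STATE_WALKING] * 2 + [STATE_STANDING] * 2)
        out = state_breakdown(pred, truth, states)
        assert out["by_state"]["walking"]["fp_share_pct"] == 100.0
        assert out["by_state"]["standing"]["fp_share_pct"] == 0.0

    def test_zero_fp_flagged_empty(self):
        truth = np.array([1, 0], dtype=bool)
        out = state_breakdown(truth, truth, np.zeros(2, dtype=int))
        assert not out["fp_shares_defined"]

    def test_shares_sum_to_100_and_match_brute_force(self, rng):
        pred = rng.integers(0, 2, 400).astype(bool)
        truth = rng.integers(0, 2, 400).astype(bool)
        states = rng.integers(0, 4, 400)
        out = state_breakdown(pred, truth, states)
        fp_total = sum(
            s["fp_share_pct"] for s in out["by_state"].values()
        )
        assert fp_total == pytest.approx(100.0, abs=1e-9)
        # brute-force tally for one state
        fp_walk = sum(
            1 for p, t, s in zip(pred, truth, states)
            if p and not t and s == STATE_WALKING
        )
        assert out["by_state"]["walking"]["fp_share_pct"] == pytest.approx(
            100.0 * fp_walk / out["n_fp"]
        )
        n_walk = int((states == STATE_WALKING).sum())
        assert out["by_state"]["walking"]["fp_rate_pct"] == pytest.approx(
            100.0 * fp_walk / n_walk
        )


class TestActiveOnly:
    def test_all_standing_rejected(self):
        with pytest.raises(ValueError):
            evaluate_active_only(
                np.zeros(5), np.zeros(5), np.full(5, STATE_STANDING)
            )

    def test_standing_fp_excluded_gives_perfect_specificity(self):
        pred = np.array([1, 1, 0, 0], dtype=bool)
        truth = np.zeros(4, dtype=bool)
        states = np.array(
            [STATE_STANDING, STATE_STANDING, STATE_WALKING, STATE_TURNING]
        )
        m = evaluate_active_only(pred, truth, states)
        assert m["specificity_pct"] == 100.0

    def test_equals_masked_metrics(self, rng):
        pred = rng.integers(0, 2, 300).astype(bool)
        truth = rng.integers(0, 2, 300).astype(bool)
        states = rng.integers(0, 4, 300)
        active = (states == STATE_WALKING) | (states == STATE_TURNING)
        expected = metrics(confusion(pred[active], truth[active]))
        assert evaluate_active_only(pred, truth, states) == expected


class TestAggregate:
    def test_population_sd_convention(self):
        # mean/SD over folds uses the population formula (divide by n)
        vals = [83.0, 77.2, 72.5, 85.9, 77.4, 86.2, 92.2]
        mean, sd = aggregate(vals)
        arr = np.array(vals)
        assert mean == pytest.approx(arr.mean())
        assert sd == pytest.approx(np.sqrt(((arr - arr.mean()) ** 2).mean()))

    def test_identical_folds_zero_sd(self):
        assert aggregate([5.0, 5.0, 5.0]) == (5.0, 0.0)

    def test_undefined_entries_skipped(self):
        mean, sd = aggregate([10.0, None, 20.0])
        assert mean == pytest.approx(15.0)

    def test_all_undefined_returns_none(self):
        assert aggregate([None, None]) is None


@pytest.fixture(scope="module")
def small_cv(fast_cohort):
    cfg = ModelConfig(epochs=2, seed=0)
    return lopo_cv(fast_cohort, mode="detection", config=cfg, master_seed=3)


class TestCrossValidation:
    """Structural checks on a tiny cohort with a short training schedule."""

    def test_one_fold_per_freezer_each_held_once(self, fast_cohort, small_cv):
        folds, agg = small_cv
        freezer_ids = [m.participant_id for m, _ in fast_cohort if m.is_freezer]
        assert sorted(f.held_out for f in folds) == sorted(freezer_ids)
        assert agg["n_folds"] == len(freezer_ids)

    def test_metrics_recomputable_from_counts(self, small_cv):
        folds, _ = small_cv
        for f in folds:
            assert f.metrics == metrics(f.counts)
            m, t = percent_time_frozen(f.counts)
            assert (f.model_pct_frozen, f.true_pct_frozen) == (m, t)

    def test_counts_cover_every_heldout_sample(self, fast_cohort, small_cv):
        folds, _ = small_cv
        sizes = {
            m.participant_id: sum(tr.n_samples for tr in trials)
            for m, trials in fast_cohort
        }
        for f in folds:
            assert f.counts.total == sizes[f.held_out]

    def test_latency_counts_match_episodes(self, fast_cohort, small_cv):
        folds, _ = small_cv
        eps = {
            m.participant_id: len(m.episodes) for m, _ in fast_cohort
        }
        for f in folds:
            assert f.n_detected + f.n_undetected == eps[f.held_out]

    def test_reproducible_under_master_seed(self, fast_cohort, small_cv):
        folds, _ = small_cv
        cfg = ModelConfig(epochs=2, seed=0)
        folds2, _ = lopo_cv(fast_cohort, mode="detection", config=cfg, master_seed=3)
        for a, b in zip(folds, folds2):
            assert a.counts == b.counts
            assert a.loss_log == b.loss_log

    def test_too_few_freezers_rejected(self, fast_cohort):
        only_one = [s for s in fast_cohort if s[0].participant_id == "P01"]
        with pytest.raises(ValueError):
            lopo_cv(only_one, config=ModelConfig(epochs=1))


class TestNonFreezerValidation:
    def test_sensitivity_undefined_specificity_defined(self, fast_cohort):
        out = non_freezer_validation(
            fast_cohort, config=ModelConfig(epochs=2, seed=0), master_seed=3
        )
        assert out["counts"].tp == out["counts"].fn == 0
        assert out["metrics"]["sensitivity_pct"] is None
        assert out["metrics"]["specificity_pct"] is not None
        # with no true positives the model percent-time-frozen is the FP rate
        c = out["counts"]
        assert out["model_pct_frozen"] == pytest.approx(
            100.0 * c.fp / (c.fp + c.tn)
        )
        assert out["true_pct_frozen"] == 0.0

    def test_no_nonfreezers_rejected(self, fast_cohort):
        freezers = [s for s in fast_cohort if s[0].is_freezer]
        with pytest.raises(ValueError):
            non_freezer_validation(freezers, config=ModelConfig(epochs=1))
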