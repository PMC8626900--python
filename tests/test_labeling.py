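import numpy as np
import pytest

from fogait import FogEpisode, apply_prefog, build_training_instances, map_video_labels
from fogait.labeling import episode_statistics
from fogait.trial_store import LABEL_FOG, LABEL_NONFOG, LABEL_PREFOG, SessionManifest

GRID = np.arange(1000) * 0.01  # 10 s trial


def ep(onset, end, tid="t"):
    return FogEpisode(onset, end, tid)


class TestMapVideoLabels:
    def test_aligned_episode(self):
        labels = map_video_labels([ep(1.0, 2.0)], GRID)
        assert np.flatnonzero(labels == LABEL_FOG).tolist() == list(range(100, 200))

    def test_offgrid_episode_snaps_to_nearest_sample(self):
        # 30 Hz annotation boundaries fall between 100 Hz samples
        labels = map_video_labels([ep(1.004, 2.004)], GRID)
        expected = np.full(1000, LABEL_NONFOG)
        i0 = int(np.argmin(np.abs(GRID - 1.004)))
        i1 = int(np.argmin(np.abs(GRID - 2.004)))
        expected[i0:i1] = LABEL_FOG
        np.testing.assert_array_equal(labels, expected)
        assert i0 == 100 and i1 == 200

    def test_no_episodes_all_nonfog(self):
        assert np.all(map_video_labels([], GRID) == LABEL_NONFOG)

    def test_episode_outside_span_raises(self):
        with pytest.raises(ValueError, match="outside trial span"):
            map_video_labels([ep(9.5, 11.0)], GRID)

    def test_thirty_hz_boundaries_against_nearest_search(self):
        # episodes drawn on the 1/30 s video grid
        for k0, k1 in [(10, 43), (55, 70), (100, 200)]:
            onset, end = k0 / 30, k1 / 30
            labels = map_video_labels([ep(onset, end)], GRID)
            i0 = int(np.argmin(np.abs(GRID - onset)))
            i1 = int(np.argmin(np.abs(GRID - end)))
            assert np.flatnonzero(labels == LABEL_FOG).tolist() == list(range(i0, i1))


class TestApplyPrefog:
    def test_long_episode_gets_two_seconds(self):
        labels = map_video_labels([ep(5.0, 8.0)], GRID)
        out = apply_prefog(labels, [ep(5.0, 8.0)], GRID)
        assert (out == LABEL_PREFOG).sum() == 200
        assert np.all(out[300:500] == LABEL_PREFOG)

    def test_short_episode_window_equals_duration(self):
        labels = map_video_labels([ep(5.0, 6.2)], GRID)
        out = apply_prefog(labels, [ep(5.0, 6.2)], GRID)
        assert (out == LABEL_PREFOG).sum() == 120

    def test_truncated_at_trial_start(self):
        labels = map_video_labels([ep(0.5, 3.5)], GRID)
        out = apply_prefog(labels, [ep(0.5, 3.5)], GRID)
        assert (out == LABEL_PREFOG).sum() == 50

    def test_truncated_at_previous_episode(self):
        eps = [ep(1.0, 4.0), ep(4.5, 7.5)]
        labels = map_video_labels(eps, GRID)
        out = apply_prefog(labels, eps, GRID)
        # second window is only the 0.5 s gap
        assert np.all(out[400:450] == LABEL_PREFOG)
        assert (out == LABEL_PREFOG).sum() == 100 + 50

    def test_never_reduces_fog_samples(self, rng):
        for _ in range(20):
            n = rng.integers(1, 4)
            starts = np.sort(rng.uniform(0.5, 8.0, n))
            eps = []
            prev_end = 0.0
            for s in starts:
                if s <= prev_end:
                    continue
                e = min(s + float(rng.uniform(0.2, 2.5)), 9.9)
                eps.append(ep(round(s, 2), round(e, 2)))
                prev_end = e + 0.1
            labels = map_video_labels(eps, GRID)
            out = apply_prefog(labels, eps, GRID)
            assert (out == LABEL_FOG).sum() == (labels == LABEL_FOG).sum()


class TestBalancer:
    def test_ample_context_one_to_one(self):
        eps = [ep(4.0, 8.0, "tr")]
        labels = map_video_labels(eps, GRID)
        (inst,) = build_training_instances(labels, eps, GRID, mode="detection")
        assert inst.n_target == 400
        assert inst.n_nontarget == 400
        # half before, half after
        assert inst.start == 400 - 200
        assert inst.stop == 800 + 200

    def test_shortfall_compensated_on_other_side(self):
        eps = [ep(0.5, 4.5, "tr")]
        labels = map_video_labels(eps, GRID)
        (inst,) = build_training_instances(labels, eps, GRID, mode="detection")
        assert inst.n_target == 400
        assert inst.n_nontarget == 400
        assert inst.start == 0  # only 0.5 s available before
        assert inst.stop == 450 + 350

    def test_tight_episodes_imbalanced_toward_target(self):
        grid = np.arange(900) * 0.01  # 9 s trial
        eps = [ep(0.0, 4.0, "tr"), ep(5.0, 9.0, "tr")]
        labels = map_video_labels(eps, grid)
        insts = build_training_instances(labels, eps, grid, mode="detection")
        assert len(insts) == 2
        for inst in insts:
            assert inst.n_target == 400
            assert inst.n_target > inst.n_nontarget

    def test_shared_context_between_close_episodes(self):
        eps = [ep(1.0, 3.0, "tr"), ep(4.0, 6.0, "tr")]
        labels = map_video_labels(eps, GRID)
        a, b = build_training_instances(labels, eps, GRID, mode="detection")
        # the 1 s gap serves as after-context of a and before-context of b
        assert a.stop > 300 and b.start < 400
        assert set(range(b.start, 400)) & set(range(300, a.stop))

    def test_one_instance_per_episode_randomized(self, rng):
        """Interval-arithmetic oracle over randomized episode layouts."""
        for _ in range(100):
            grid = np.arange(3000) * 0.01
            n = int(rng.integers(1, 5))
            eps = []
            cursor = 0.5
            for _ in range(n):
                onset = cursor + float(rng.uniform(0.1, 4.0))
                dur = float(rng.uniform(0.3, 3.0))
                end = onset + dur
                if end > 29.0:
                    break
                eps.append(ep(round(onset, 2), round(end, 2)))
                cursor = end
            if not eps:
                continue
            labels = map_video_labels(eps, grid)
            insts = build_training_instances(labels, eps, grid, mode="detection")
            assert len(insts) == len(eps)
            total_fog = int((labels == LABEL_FOG).sum())
            assert sum(i.n_target for i in insts) == total_fog
            for inst, e in zip(insts, sorted(eps, key=lambda x: x.onset_s)):
                # instance is contiguous and inside the trial
                assert 0 <= inst.start < inst.stop <= len(grid)
                assert len(inst.targets) == inst.stop - inst.start
                # targets exactly mark the episode's samples
                i0 = int(round(e.onset_s * 100))
                i1 = int(round(e.end_s * 100))
                np.testing.assert_array_equal(
                    np.flatnonzero(inst.targets) + inst.start, np.arange(i0, i1)
                )
                # 1:1 whenever the surrounding gaps could supply the context
                before_gap = i0 - max(
                    0, *(int(round(p.end_s * 100)) for p in eps if p.end_s <= e.onset_s)
                ) if any(p.end_s <= e.onset_s for p in eps) else i0
                after_gap = (
                    min(
                        [int(round(p.onset_s * 100)) for p in eps if p.onset_s >= e.end_s]
                        + [len(grid)]
                    )
                    - i1
                )
                if before_gap + after_gap >= inst.n_target:
                    assert inst.n_nontarget == inst.n_target

    def test_prediction_mode_targets_include_prefog(self):
        eps = [ep(5.0, 8.0, "tr")]
        labels = apply_prefog(map_video_labels(eps, GRID), eps, GRID)
        (inst,) = build_training_instances(labels, eps, GRID, mode="prediction")
        assert inst.n_target == 500  # 2 s PreFOG + 3 s FOG
        assert inst.n_nontarget == 500

    def test_prediction_neighbor_prefog_not_context(self):
        eps = [ep(1.0, 2.0, "tr"), ep(6.0, 7.0, "tr")]
        labels = apply_prefog(map_video_labels(eps, GRID), eps, GRID)
        a, _ = build_training_instances(labels, eps, GRID, mode="prediction")
        # after-context of the first instance must stop before the second
        # episode's PreFOG window at 5.0 s
        assert a.stop <= 500

    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError):
            build_training_instances(np.zeros(10), [], GRID[:10], mode="other")


def test_episode_statistics_matches_manifest():
    m = SessionManifest(
        "P05",
        trial_ids=["a"],
        episodes=[ep(1.0, 2.0, "a"), ep(3.0, 6.0, "a")],
    )
    stats = episode_statistics(m)
    assert stats["n_episodes"] == 2
    assert stats["mean_duration_s"] == pytest.approx(2.0)
    assert stats["total_duration_s"] == pytest.approx(4.0)
    empty = episode_statistics(SessionManifest("P04"))
    assert empty["n_episodes"] == 0 and empty["mean_duration_s"] is None
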