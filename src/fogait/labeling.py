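"""Label handling: video-rate annotation mapping, Pre-FOG relabeling, and
episode-centric training-set balancing.

Freeze annotations come from video at 30 Hz; samples are at 100 Hz. Each
sample gets the label of its nearest-aligned annotation boundary, so every
datapoint carries exactly one label.

For prediction models the window immediately before each freeze is
relabeled Pre-FOG: 2 s for episodes lasting 2 s or longer, otherwise a
window equal to the episode's own duration.

Balancing builds one contiguous training instance per freeze episode: the
episode's target samples plus non-target context split half before / half
after, compensating one-sided shortfalls on the other side, so the
target:non-target ratio is 1:1 whenever enough context exists. Validation
data are never balanced.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .trial_store import (
    LABEL_FOG,
    LABEL_NONFOG,
    LABEL_PREFOG,
    FogEpisode,
    SessionManifest,
)

__all__ = [
    "TrainingInstance",
    "map_video_labels",
    "apply_prefog",
    "build_training_instances",
    "episode_statistics",
]

PREFOG_MAX_S = 2.0


@dataclass
class TrainingInstance:
    """One contiguous labeled sub-sequence built around one freeze episode.

    ``start``/``stop`` index into the parent trial (half-open). ``targets``
    is the per-sample binary target over that range: 1 for the target class
    (FOG, or PreFOG+FOG in prediction mode), 0 for non-target.
    """

    trial_id: str
    start: int
    stop: int
    targets: np.ndarray

    def __post_init__(self) -> None:
        self.targets = np.asarray(self.targets, dtype=np.int64)
        if len(self.targets) != self.stop - self.start:
            raise ValueError("target vector length does not match index range")

    @property
    def n_target(self) -> int:
        return int(self.targets.sum())

    @property
    def n_nontarget(self) -> int:
        return int(len(self.targets) - self.targets.sum())


def _nearest_index(timestamps: np.ndarray, t: float) -> int:
    """Nearest 100 Hz grid index for t; may equal len(timestamps) so a
    half-open range can end one past the last sample."""
    idx = int(round((t - timestamps[0]) / 0.01))
    return max(0, min(idx, len(timestamps)))


def map_video_labels(
    episodes: list[FogEpisode], timestamps: np.ndarray
) -> np.ndarray:
    """Map [onset, end) freeze annotations onto the 100 Hz sample grid.

    Onset and end are each snapped to the nearest sample timestamp; samples
    in the snapped half-open range are labeled FOG, everything else NonFOG.
    """
    timestamps = np.asarray(timestamps, dtype=np.float64)
    labels = np.full(len(timestamps), LABEL_NONFOG, dtype=np.int64)
    t0, t1 = timestamps[0], timestamps[-1]
    for ep in episodes:
        if ep.onset_s < t0 - 1e-9 or ep.end_s > t1 + 0.01 + 1e-9:
            raise ValueError(
                f"episode [{ep.onset_s}, {ep.end_s}) lies outside trial span "
                f"[{t0}, {t1 + 0.01}) of trial {ep.trial_id}"
            )
        i0 = _nearest_index(timestamps, ep.onset_s)
        i1 = _nearest_index(timestamps, ep.end_s)
        labels[i0:i1] = LABEL_FOG
    return labels


def apply_prefog(
    labels: np.ndarray,
    episodes: list[FogEpisode],
    timestamps: np.ndarray,
    prefog_max_s: float = PREFOG_MAX_S,
) -> np.ndarray:
    """Relabel the window before each freeze as Pre-FOG.

    The window is min(episode duration, ``prefog_max_s``) seconds, truncated
    at the trial start and at the end of any earlier episode. FOG labels are
    never overwritten, so the number of FOG samples is unchanged.
    """
    labels = np.asarray(labels, dtype=np.int64).copy()
    timestamps = np.asarray(timestamps, dtype=np.float64)
    prev_end_idx = 0
    for ep in sorted(episodes, key=lambda e: e.onset_s):
        i0 = _nearest_index(timestamps, ep.onset_s)
        window = min(ep.duration_s, prefog_max_s)
        n_pre = int(round(window / 0.01))
        start = max(0, prev_end_idx, i0 - n_pre)
        seg = labels[start:i0]
        seg[seg != LABEL_FOG] = LABEL_PREFOG
        labels[start:i0] = seg
        prev_end_idx = _nearest_index(timestamps, ep.end_s)
    return labels


def build_training_instances(
    labels: np.ndarray,
    episodes: list[FogEpisode],
    timestamps: np.ndarray,
    mode: str = "detection",
    trial_id: str | None = None,
) -> list[TrainingInstance]:
    """Build one balanced training instance per freeze episode of a trial.

    ``mode='detection'``: target class is FOG. ``mode='prediction'``:
    target class is PreFOG plus FOG (labels must already be
    Pre-FOG-relabeled); each episode's target block includes its own
    Pre-FOG window, and a neighboring episode's Pre-FOG samples are never
    used as NonFOG context.

    Context is split half before / half after the target block (before
    rounded down, after up); a shortfall on one side is compensated on the
    other; when the surrounding NonFOG runs cannot supply enough, the
    instance keeps all available context and stays imbalanced toward the
    target class. NonFOG samples between close episodes may be shared by
    both neighbors.
    """
    if mode not in ("detection", "prediction"):
        raise ValueError(f"mode must be 'detection' or 'prediction', got {mode!r}")
    labels = np.asarray(labels, dtype=np.int64)
    timestamps = np.asarray(timestamps, dtype=np.float64)
    context_ok = labels == LABEL_NONFOG

    ordered = sorted(episodes, key=lambda e: e.onset_s)
    # per-episode target blocks [lo, hi) in sample indices
    blocks: list[tuple[int, int]] = []
    prev_end_idx = 0
    for ep in ordered:
        i0 = _nearest_index(timestamps, ep.onset_s)
        i1 = _nearest_index(timestamps, ep.end_s)
        lo = i0
        if mode == "prediction":
            n_pre = int(round(min(ep.duration_s, PREFOG_MAX_S) / 0.01))
            lo = max(0, prev_end_idx, i0 - n_pre)
        blocks.append((lo, i1))
        prev_end_idx = i1

    tid = trial_id or (ordered[0].trial_id if ordered else "")
    instances: list[TrainingInstance] = []
    for lo, hi in blocks:
        n_target = hi - lo
        if n_target <= 0:
            warnings.warn(
                f"episode in trial {tid} has zero target samples; skipped",
                stacklevel=2,
            )
            continue
        # contiguous usable context immediately before / after the block
        avail_before = 0
        i = lo - 1
        while i >= 0 and context_ok[i]:
            avail_before += 1
            i -= 1
        avail_after = 0
        i = hi
        while i < len(labels) and context_ok[i]:
            avail_after += 1
            i += 1

        want_before = n_target // 2
        want_after = n_target - want_before
        take_before = min(want_before, avail_before)
        take_after = min(want_after, avail_after)
        shortfall = (want_before - take_before) + (want_after - take_after)
        if shortfall > 0:
            extra_after = min(shortfall, avail_after - take_after)
            take_after += extra_after
            shortfall -= extra_after
            extra_before = min(shortfall, avail_before - take_before)
            take_before += extra_before

        start, stop = lo - take_before, hi + take_after
        targets = np.zeros(stop - start, dtype=np.int64)
        targets[lo - start : hi - start] = 1
        instances.append(
            TrainingInstance(trial_id=tid, start=start, stop=stop, targets=targets)
        )
    return instances


def episode_statistics(manifest: SessionManifest) -> dict:
    """Cohort-description helper: freeze count, mean/SD/total duration (s)."""
    durations = np.array([e.duration_s for e in manifest.episodes])
    if len(durations) == 0:
        return {
            "participant_id": manifest.participant_id,
            "n_episodes": 0,
            "mean_duration_s": None,
            "sd_duration_s": None,
            "total_duration_s": 0.0,
        }
    return {
        "participant_id": manifest.participant_id,
        "n_episodes": int(len(durations)),
        "mean_duration_s": float(durations.mean()),
        "sd_duration_s": float(durations.std()),
        "total_duration_s": float(durations.sum()),
    }
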