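"""Evaluation protocols and metrics for freeze classification.

Implements datapoint-level confusion metrics (sensitivity, specificity,
precision, F1), percent-time-frozen, episode-level detection latency,
activity-state error breakdowns, leave-one-freezer-out cross-validation,
and all-non-freezer validation. Validation data are never balanced; the
classifier runs over every sample of every held-out trial.

Conventions that match how such results are reported:

* fold aggregates are the mean and *population* standard deviation
  (divide by n, not n-1) over folds;
* detection latency is signed: the start of the predicted freeze run that
  intersects a true episode, minus the true onset. A run may begin before
  onset, so latency can be negative (the freeze was anticipated);
* undetected episodes are excluded from latency averages and reported as
  separate counts;
* metrics with a zero denominator are flagged undefined (None) and
  excluded from aggregation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .features import FeatureSeries, extract_features
from .labeling import apply_prefog, build_training_instances
from .model import (
    FogClassifier,
    ModelConfig,
    build_model,
    classify,
    fit_normalizer,
    train,
)
from .trial_store import (
    LABEL_FOG,
    LABEL_PREFOG,
    SAMPLE_DT_S,
    STATE_NAMES,
    STATE_STANDING,
    STATE_TURNING,
    STATE_UNDEFINED,
    STATE_WALKING,
    FogEpisode,
    SessionManifest,
    Trial,
)

__all__ = [
    "ConfusionCounts",
    "FoldResult",
    "confusion",
    "metrics",
    "percent_time_frozen",
    "detection_latency",
    "state_breakdown",
    "evaluate_active_only",
    "aggregate",
    "lopo_cv",
    "non_freezer_validation",
]

Cohort = list[tuple[SessionManifest, list[Trial]]]


@dataclass
class ConfusionCounts:
    """Datapoint-level confusion counts; positive class = freeze target."""

    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )


def confusion(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Tally binary per-sample predictions against binary truth."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {truth.shape}")
    return ConfusionCounts(
        tp=int(np.sum(pred & truth)),
        tn=int(np.sum(~pred & ~truth)),
        fp=int(np.sum(pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
    )


def metrics(counts: ConfusionCounts) -> dict[str, float | None]:
    """Sensitivity, specificity, precision (percent) and F1 (0..1).

    F1 is the harmonic mean of sensitivity and precision. Any metric whose
    denominator is zero is returned as None (undefined).
    """
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    sens = tp / (tp + fn) if tp + fn > 0 else None
    spec = tn / (tn + fp) if tn + fp > 0 else None
    prec = tp / (tp + fp) if tp + fp > 0 else None
    if sens is not None and prec is not None and (sens + prec) > 0:
        f1 = 2.0 * sens * prec / (sens + prec)
    else:
        f1 = None
    return {
        "sensitivity_pct": None if sens is None else 100.0 * sens,
        "specificity_pct": None if spec is None else 100.0 * spec,
        "precision_pct": None if prec is None else 100.0 * prec,
        "f1": f1,
    }


def percent_time_frozen(counts: ConfusionCounts) -> tuple[float, float]:
    """(model, true) percent time frozen.

    model = (TP+FP)/total, true = (TP+FN)/total, both as percentages; the
    true value is model-independent label prevalence.
    """
    if counts.total == 0:
        raise ValueError("percent time frozen undefined on zero datapoints")
    model = 100.0 * (counts.tp + counts.fp) / counts.total
    true = 100.0 * (counts.tp + counts.fn) / counts.total
    return model, true


def _pred_runs(pred: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) ranges of maximal positive-prediction runs."""
    mask = np.asarray(pred).astype(bool)
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False])).astype(np.int8)
    edges = np.diff(padded)
    return list(
        zip(np.flatnonzero(edges == 1).tolist(), np.flatnonzero(edges == -1).tolist())
    )


def detection_latency(
    pred: np.ndarray,
    episodes: list[FogEpisode],
    timestamps: np.ndarray,
) -> list[dict]:
    """Episode-level detection outcome and signed latency for one trial.

    An episode counts as detected if at least one positively classified
    sample falls inside its true [onset, end) window. Latency is measured
    from the start of the maximal contiguous predicted run containing the
    earliest in-window positive sample, so it is negative when the run
    began before the true onset. A run spanning two true episodes is
    credited to the first; a later episode covered only by that run gets
    latency from its first in-window positive sample (>= 0).
    """
    pred = np.asarray(pred).astype(bool)
    timestamps = np.asarray(timestamps, dtype=np.float64)
    runs = _pred_runs(pred)
    assigned: set[int] = set()
    out = []
    for ep in sorted(episodes, key=lambda e: e.onset_s):
        i0 = int(np.searchsorted(timestamps, ep.onset_s - 1e-9))
        i1 = int(np.searchsorted(timestamps, ep.end_s - 1e-9))
        window_pred = np.flatnonzero(pred[i0:i1])
        if len(window_pred) == 0:
            out.append({"episode": ep, "detected": False, "latency_s": None})
            continue
        first_hit = i0 + int(window_pred[0])
        run_idx = next(
            k for k, (a, b) in enumerate(runs) if a <= first_hit < b
        )
        if run_idx in assigned:
            start_idx = first_hit  # run already credited to an earlier episode
        else:
            assigned.add(run_idx)
            start_idx = runs[run_idx][0]
        latency = timestamps[start_idx] - ep.onset_s
        out.append({"episode": ep, "detected": True, "latency_s": float(latency)})
    return out


_ALL_STATES = (STATE_WALKING, STATE_TURNING, STATE_STANDING, STATE_UNDEFINED)


def state_breakdown(
    pred: np.ndarray, truth: np.ndarray, states: np.ndarray
) -> dict:
    """Distribute false positives / negatives over activity states.

    Returns, per state, the share of all FP (and FN) occurring in that
    state (shares sum to 100% when any exist) and the per-state FP rate
    (FP in state / samples labeled with that state).
    """
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    states = np.asarray(states)
    fp_mask = pred & ~truth
    fn_mask = ~pred & truth
    n_fp, n_fn = int(fp_mask.sum()), int(fn_mask.sum())
    out: dict = {"n_fp": n_fp, "n_fn": n_fn, "by_state": {}}
    for code in _ALL_STATES:
        name = STATE_NAMES[code]
        in_state = states == code
        fp_here = int(np.sum(fp_mask & in_state))
        fn_here = int(np.sum(fn_mask & in_state))
        out["by_state"][name] = {
            "fp_share_pct": 100.0 * fp_here / n_fp if n_fp else 0.0,
            "fn_share_pct": 100.0 * fn_here / n_fn if n_fn else 0.0,
            "fp_rate_pct": (
                100.0 * fp_here / int(in_state.sum()) if in_state.any() else None
            ),
        }
    out["fp_shares_defined"] = n_fp > 0
    out["fn_shares_defined"] = n_fn > 0
    return out


def evaluate_active_only(
    pred: np.ndarray, truth: np.ndarray, states: np.ndarray
) -> dict[str, float | None]:
    """Metrics restricted to active states (walking and turning)."""
    states = np.asarray(states)
    active = (states == STATE_WALKING) | (states == STATE_TURNING)
    if not active.any():
        raise ValueError("no active-state samples to evaluate")
    return metrics(confusion(np.asarray(pred)[active], np.asarray(truth)[active]))


def aggregate(values: list[float | None]) -> tuple[float, float] | None:
    """Mean and population SD over folds, skipping undefined entries."""
    vals = np.array([v for v in values if v is not None], dtype=np.float64)
    if len(vals) == 0:
        return None
    return float(vals.mean()), float(vals.std())  # ddof=0: population SD


# ---------------------------------------------------------------------------
# cross-validation protocols


@dataclass
class FoldResult:
    """Everything measured on one held-out participant."""

    held_out: str
    counts: ConfusionCounts
    metrics: dict
    active_only: dict
    latencies: list[dict]
    n_detected: int
    n_undetected: int
    breakdown: dict
    model_pct_frozen: float
    true_pct_frozen: float
    loss_log: list[float] = field(default_factory=list)


def _truth_vector(labels: np.ndarray, mode: str) -> np.ndarray:
    if mode == "detection":
        return labels == LABEL_FOG
    return (labels == LABEL_FOG) | (labels == LABEL_PREFOG)


def _prepare_labels(manifest: SessionManifest, trial: Trial, mode: str) -> np.ndarray:
    if mode == "detection":
        return trial.labels
    return apply_prefog(
        trial.labels, manifest.episodes_for_trial(trial.trial_id), trial.timestamps
    )


def _training_sequences(
    sessions: Cohort,
    feature_cache: dict[str, FeatureSeries],
    mode: str,
) -> list[tuple[np.ndarray, np.ndarray]]:
    sequences = []
    for manifest, trials in sessions:
        for trial in trials:
            eps = manifest.episodes_for_trial(trial.trial_id)
            if not eps:
                continue
            labels = _prepare_labels(manifest, trial, mode)
            instances = build_training_instances(
                labels, eps, trial.timestamps, mode=mode, trial_id=trial.trial_id
            )
            feats = feature_cache[trial.trial_id].values
            for inst in instances:
                sequences.append((feats[inst.start : inst.stop], inst.targets))
    return sequences


def _evaluate_fold(
    model: FogClassifier,
    held: tuple[SessionManifest, list[Trial]],
    feature_cache: dict[str, FeatureSeries],
    mode: str,
) -> FoldResult:
    manifest, trials = held
    counts = ConfusionCounts()
    preds_all, truth_all, states_all = [], [], []
    latencies: list[dict] = []
    for trial in trials:
        feats = feature_cache[trial.trial_id].values
        pred = classify(model, feats)
        labels = _prepare_labels(manifest, trial, mode)
        truth = _truth_vector(labels, mode)
        counts = counts + confusion(pred, truth)
        preds_all.append(pred)
        truth_all.append(truth)
        states_all.append(trial.states)
        latencies.extend(
            detection_latency(
                pred, manifest.episodes_for_trial(trial.trial_id), trial.timestamps
            )
        )
    pred_cat = np.concatenate(preds_all)
    truth_cat = np.concatenate(truth_all)
    states_cat = np.concatenate(states_all)
    model_pct, true_pct = percent_time_frozen(counts)
    n_detected = sum(1 for d in latencies if d["detected"])
    return FoldResult(
        held_out=manifest.participant_id,
        counts=counts,
        metrics=metrics(counts),
        active_only=evaluate_active_only(pred_cat, truth_cat, states_cat),
        latencies=latencies,
        n_detected=n_detected,
        n_undetected=len(latencies) - n_detected,
        breakdown=state_breakdown(pred_cat, truth_cat, states_cat),
        model_pct_frozen=model_pct,
        true_pct_frozen=true_pct,
        loss_log=list(model.loss_log),
    )


def _fold_seed(master_seed: int, index: int) -> int:
    return int(
        np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % (2**31)
    )


def _feature_cache(cohort: Cohort) -> dict[str, FeatureSeries]:
    cache: dict[str, FeatureSeries] = {}
    for _, trials in cohort:
        for trial in trials:
            cache[trial.trial_id] = extract_features(trial)
    return cache


def _fit_fold_model(
    training_sessions: Cohort,
    feature_cache: dict[str, FeatureSeries],
    mode: str,
    config: ModelConfig,
    seed: int,
) -> FogClassifier:
    sequences = _training_sequences(training_sessions, feature_cache, mode)
    if not sequences:
        raise ValueError("training split contains no freeze episodes")
    stats = fit_normalizer([X for X, _ in sequences])
    model = build_model(replace(config, seed=seed))
    train(model, sequences, stats)
    return model


def lopo_cv(
    cohort: Cohort,
    mode: str = "detection",
    config: ModelConfig | None = None,
    master_seed: int = 0,
) -> tuple[list[FoldResult], dict]:
    """Leave-one-freezer-out cross-validation.

    Each freezer is held out once; the model trains on balanced instances
    from every other freezer (normalization refit per fold) and classifies
    every sample of the held-out participant's unbalanced trials.
    """
    config = config or ModelConfig()
    freezers = [s for s in cohort if s[0].is_freezer]
    if len(freezers) < 2:
        raise ValueError("leave-one-freezer-out needs at least 2 freezers")
    cache = _feature_cache(cohort)
    folds: list[FoldResult] = []
    for i, held in enumerate(freezers):
        training = [s for j, s in enumerate(freezers) if j != i]
        model = _fit_fold_model(
            training, cache, mode, config, _fold_seed(master_seed, i)
        )
        folds.append(_evaluate_fold(model, held, cache, mode))

    agg: dict = {"n_folds": len(folds)}
    for key in ("sensitivity_pct", "specificity_pct", "precision_pct", "f1"):
        agg[key] = aggregate([f.metrics[key] for f in folds])
        agg["active_only_" + key] = aggregate([f.active_only[key] for f in folds])
    agg["n_episodes"] = sum(f.n_detected + f.n_undetected for f in folds)
    agg["n_detected"] = sum(f.n_detected for f in folds)
    det_lat = [
        d["latency_s"] for f in folds for d in f.latencies if d["detected"]
    ]
    agg["mean_latency_s"] = float(np.mean(det_lat)) if det_lat else None
    agg["model_pct_frozen"] = aggregate([f.model_pct_frozen for f in folds])
    agg["true_pct_frozen"] = aggregate([f.true_pct_frozen for f in folds])
    return folds, agg


def non_freezer_validation(
    cohort: Cohort,
    mode: str = "detection",
    config: ModelConfig | None = None,
    master_seed: int = 0,
) -> dict:
    """Train on all freezers, validate on every non-freezer's data.

    Non-freezers contribute no positive samples, so sensitivity is
    undefined; specificity measures the false-positive behavior, and model
    percent time frozen equals the FP rate.
    """
    config = config or ModelConfig()
    freezers = [s for s in cohort if s[0].is_freezer]
    non_freezers = [s for s in cohort if not s[0].is_freezer]
    if not non_freezers:
        raise ValueError("cohort contains no non-freezers")
    cache = _feature_cache(cohort)
    model = _fit_fold_model(
        freezers, cache, mode, config, _fold_seed(master_seed, 10_000)
    )
    counts = ConfusionCounts()
    preds_all, truth_all, states_all = [], [], []
    for manifest, trials in non_freezers:
        for trial in trials:
            pred = classify(model, cache[trial.trial_id].values)
            labels = _prepare_labels(manifest, trial, mode)
            truth = _truth_vector(labels, mode)
            counts = counts + confusion(pred, truth)
            preds_all.append(pred)
            truth_all.append(truth)
            states_all.append(trial.states)
    model_pct, true_pct = percent_time_frozen(counts)
    return {
        "counts": counts,
        "metrics": metrics(counts),
        "breakdown": state_breakdown(
            np.concatenate(preds_all),
            np.concatenate(truth_all),
            np.concatenate(states_all),
        ),
        "model_pct_frozen": model_pct,
        "true_pct_frozen": true_pct,
    }
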