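"""The 16 per-timestep plantar-pressure features.

Per foot and per timestamp: center-of-pressure (COP) x/y coordinates (mm),
COP x/y velocity (cm/s), COP x/y acceleration (cm/s^2), total ground
reaction force (GRF; the sum of all cell pressures, kPa), and the fraction
of the two-foot GRF total carried by that foot. No signal filtering is
applied anywhere: derivatives are raw first differences at the 0.01 s
sample spacing, exactly as a real-time system would compute them.

COP is undefined while a foot carries no pressure (swing phase). The
last defined COP value is held across such gaps — so velocity through a
gap is zero rather than a spike — and a per-timestamp validity mask
records which samples involved a held value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trial_store import CELL_PITCH_MM, GRID_COLS, GRID_ROWS, SAMPLE_DT_S, Trial

__all__ = [
    "FEATURE_NAMES",
    "FeatureSeries",
    "cop_xy",
    "cop_series",
    "cop_velocity",
    "cop_acceleration",
    "total_grf",
    "grf_fraction",
    "extract_features",
]

#: Fixed column order of the feature matrix.
FEATURE_NAMES = [
    "cop_x_left_mm",
    "cop_y_left_mm",
    "cop_x_right_mm",
    "cop_y_right_mm",
    "cop_vx_left_cms",
    "cop_vy_left_cms",
    "cop_vx_right_cms",
    "cop_vy_right_cms",
    "cop_ax_left_cms2",
    "cop_ay_left_cms2",
    "cop_ax_right_cms2",
    "cop_ay_right_cms2",
    "grf_left_kpa",
    "grf_right_kpa",
    "grf_frac_left",
    "grf_frac_right",
]

_MM_PER_CM = 10.0


@dataclass
class FeatureSeries:
    """T x 16 feature matrix for one trial, plus a per-sample validity mask.

    ``valid[t]`` is False where any feature at ``t`` involved an undefined
    COP (unloaded foot) and therefore a held value.
    """

    trial_id: str
    values: np.ndarray  # (T, 16) float64
    valid: np.ndarray  # (T,) bool

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.values.ndim != 2 or self.values.shape[1] != len(FEATURE_NAMES):
            raise ValueError(
                f"feature matrix must have {len(FEATURE_NAMES)} columns, "
                f"got shape {self.values.shape}"
            )
        if len(self.valid) != len(self.values):
            raise ValueError("validity mask length mismatch")

    def __len__(self) -> int:
        return len(self.values)


def cop_xy(frame: np.ndarray) -> tuple[float, float] | None:
    """COP of one frame as (x_mm, y_mm); None when total pressure is 0.

    The COP is the pressure-weighted mean cell index per axis times the
    5.08 mm cell pitch. x runs over columns (medial->lateral), y over rows
    (heel->toe).
    """
    frame = np.asarray(frame, dtype=np.float64)
    total = frame.sum()
    if total <= 0:
        return None
    rows = np.arange(GRID_ROWS, dtype=np.float64)
    cols = np.arange(GRID_COLS, dtype=np.float64)
    y = float((frame.sum(axis=1) @ rows) / total) * CELL_PITCH_MM
    x = float((frame.sum(axis=0) @ cols) / total) * CELL_PITCH_MM
    return x, y


def _cop_series_one_foot(frames: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-foot COP series with hold-last across unloaded gaps.

    Returns (x_mm, y_mm, defined) where ``defined[t]`` is True iff the foot
    carried pressure at t. Leading undefined samples (before the first
    loaded frame) take the first defined value; an all-unloaded foot
    yields zeros.
    """
    frames = np.asarray(frames, dtype=np.float64)
    totals = frames.sum(axis=(1, 2))
    defined = totals > 0
    rows = np.arange(GRID_ROWS, dtype=np.float64)
    cols = np.arange(GRID_COLS, dtype=np.float64)
    with np.errstate(invalid="ignore", divide="ignore"):
        y = (frames.sum(axis=2) @ rows) / totals * CELL_PITCH_MM
        x = (frames.sum(axis=1) @ cols) / totals * CELL_PITCH_MM
    if not defined.all():
        if not defined.any():
            return np.zeros_like(totals), np.zeros_like(totals), defined
        # forward-fill indices of the last defined sample
        idx = np.where(defined, np.arange(len(totals)), -1)
        idx = np.maximum.accumulate(idx)
        first = np.argmax(defined)
        idx[idx < 0] = first  # back-fill the leading gap
        x = x[idx]
        y = y[idx]
    return x, y, defined


def cop_series(frames: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Public wrapper around the per-foot COP series (x_mm, y_mm, defined)."""
    return _cop_series_one_foot(frames)


def cop_velocity(cop_mm: np.ndarray) -> np.ndarray:
    """First difference of a COP coordinate series, in cm/s.

    v[t] = (cop[t] - cop[t-1]) / 0.01 s with mm -> cm conversion; v[0] = 0
    by convention so the series keeps full length.
    """
    cop_mm = np.asarray(cop_mm, dtype=np.float64)
    v = np.zeros_like(cop_mm)
    if len(cop_mm) >= 2:
        v[1:] = np.diff(cop_mm) / _MM_PER_CM / SAMPLE_DT_S
    return v


def cop_acceleration(velocity_cms: np.ndarray) -> np.ndarray:
    """First difference of a COP velocity series, in cm/s^2.

    a[t] = (v[t] - v[t-1]) / 0.01 s; a[0] = a[1] = 0 by convention (v[0] is
    itself a boundary fill).
    """
    velocity_cms = np.asarray(velocity_cms, dtype=np.float64)
    a = np.zeros_like(velocity_cms)
    if len(velocity_cms) >= 3:
        a[2:] = np.diff(velocity_cms[1:]) / SAMPLE_DT_S
    return a


def total_grf(frame: np.ndarray) -> float:
    """Sum of all 1260 cell pressures for one frame (kPa-sum GRF proxy)."""
    return float(np.asarray(frame, dtype=np.float64).sum())


def grf_fraction(grf_left: float, grf_right: float) -> tuple[float, float]:
    """Per-foot share of the two-foot GRF total; (0.5, 0.5) when both are 0."""
    total = grf_left + grf_right
    if total <= 0:
        return 0.5, 0.5
    return grf_left / total, grf_right / total


def extract_features(trial: Trial) -> FeatureSeries:
    """Compute the T x 16 feature matrix for one trial.

    Column order is :data:`FEATURE_NAMES`. The validity mask is False at
    samples where either foot's COP was undefined (held), and at the one
    sample after a gap closes (whose velocity spans the gap).
    """
    xl, yl, dl = _cop_series_one_foot(trial.left_frames)
    xr, yr, dr = _cop_series_one_foot(trial.right_frames)

    grf_l = trial.left_frames.astype(np.float64).sum(axis=(1, 2))
    grf_r = trial.right_frames.astype(np.float64).sum(axis=(1, 2))
    total = grf_l + grf_r
    frac_l = np.full_like(grf_l, 0.5)
    frac_r = np.full_like(grf_r, 0.5)
    loaded = total > 0
    frac_l[loaded] = grf_l[loaded] / total[loaded]
    frac_r[loaded] = grf_r[loaded] / total[loaded]

    cols = [xl, yl, xr, yr]
    vels = [cop_velocity(c) for c in cols]
    accs = [cop_acceleration(v) for v in vels]
    values = np.column_stack(cols + vels + accs + [grf_l, grf_r, frac_l, frac_r])

    defined = dl & dr
    valid = defined.copy()
    if len(valid) >= 2:
        # the sample closing a gap differentiates across held values
        valid[1:] &= defined[:-1]
    return FeatureSeries(trial_id=trial.trial_id, values=values, valid=valid)
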