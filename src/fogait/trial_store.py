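"""On-disk and in-memory representation of plantar-pressure walking trials.

A recording session consists of walking trials. Each trial holds, per foot,
a sequence of 60x21 pressure frames (kPa) sampled at 100 Hz, together with
per-sample class labels, per-sample activity states, and freeze-episode
annotations kept at the session level.

Storage layout: one HDF5 file per trial (datasets ``/left``, ``/right``,
``/timestamps``, ``/labels``, ``/states``; identifying metadata as root
attributes) plus one JSON manifest per session listing trials and freeze
episodes. The format is self-describing and language-portable.

Coordinate convention (fixed here, applied everywhere): row index 0 is the
heel (posterior), rows increase toward the toes; column index 0 is medial.
The cell pitch is 5.08 mm in both directions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "GRID_ROWS",
    "GRID_COLS",
    "CELL_PITCH_MM",
    "SAMPLE_RATE_HZ",
    "LABEL_NONFOG",
    "LABEL_FOG",
    "LABEL_PREFOG",
    "STATE_WALKING",
    "STATE_TURNING",
    "STATE_STANDING",
    "STATE_UNDEFINED",
    "Trial",
    "FogEpisode",
    "SessionManifest",
    "TrialValidationError",
    "TrialFormatError",
    "validate_frame",
    "save_trial",
    "load_trial",
    "save_manifest",
    "load_manifest",
]

GRID_ROWS = 60
GRID_COLS = 21
CELL_PITCH_MM = 5.08
SAMPLE_RATE_HZ = 100.0
SAMPLE_DT_S = 0.01

# Stable integer codes for bit-exact files.
LABEL_NONFOG = 0
LABEL_FOG = 1
LABEL_PREFOG = 2

STATE_WALKING = 0
STATE_TURNING = 1
STATE_STANDING = 2
STATE_UNDEFINED = 3

STATE_NAMES = {
    STATE_WALKING: "walking",
    STATE_TURNING: "turning",
    STATE_STANDING: "standing",
    STATE_UNDEFINED: "undefined",
}


class TrialValidationError(ValueError):
    """A trial violates one of its structural invariants."""


class TrialFormatError(ValueError):
    """A trial file does not conform to the container format."""


def validate_frame(frame: np.ndarray) -> None:
    """Check a single pressure frame: exact 60x21 shape, no negative cells."""
    frame = np.asarray(frame)
    if frame.shape != (GRID_ROWS, GRID_COLS):
        raise TrialFormatError(
            f"pressure frame must be {GRID_ROWS}x{GRID_COLS}, got {frame.shape}"
        )
    if np.any(frame < 0):
        raise TrialValidationError("pressure frame contains negative cell values")


@dataclass
class Trial:
    """One unbroken 100 Hz walking-trial time series for both feet.

    Attributes
    ----------
    trial_id, participant_id : str
        Identifiers; unique within a session / cohort respectively.
    timestamps : (T,) float64 array
        Strictly increasing seconds on a 0.01 s grid.
    left_frames, right_frames : (T, 60, 21) arrays, kPa
        Per-foot pressure frames; non-negative.
    labels : (T,) integer array
        Per-sample class codes (NonFOG=0, FOG=1, PreFOG=2).
    states : (T,) integer array
        Per-sample activity codes (walking=0, turning=1, standing=2,
        undefined=3).
    condition : str
        Trial condition tag (baseline / verbal / motor / dual).
    """

    trial_id: str
    participant_id: str
    timestamps: np.ndarray
    left_frames: np.ndarray
    right_frames: np.ndarray
    labels: np.ndarray
    states: np.ndarray
    condition: str = "baseline"

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.float64)
        self.left_frames = np.asarray(self.left_frames)
        self.right_frames = np.asarray(self.right_frames)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.states = np.asarray(self.states, dtype=np.int64)
        self.validate()

    @property
    def n_samples(self) -> int:
        return len(self.timestamps)

    @property
    def duration_s(self) -> float:
        return self.n_samples * SAMPLE_DT_S

    def validate(self) -> None:
        T = len(self.timestamps)
        for name in ("left_frames", "right_frames", "labels", "states"):
            arr = getattr(self, name)
            if len(arr) != T:
                raise TrialValidationError(
                    f"{name} has length {len(arr)}, expected {T} (timestamps)"
                )
        for name in ("left_frames", "right_frames"):
            arr = getattr(self, name)
            if arr.ndim != 3 or arr.shape[1:] != (GRID_ROWS, GRID_COLS):
                raise TrialFormatError(
                    f"{name} must be (T, {GRID_ROWS}, {GRID_COLS}), got {arr.shape}"
                )
            if np.any(arr < 0):
                raise TrialValidationError(f"{name} contains negative pressure values")
        if T >= 2:
            dt = np.diff(self.timestamps)
            if np.any(dt <= 0):
                raise TrialValidationError("timestamps are not strictly increasing")
            if np.any(np.abs(dt - SAMPLE_DT_S) > 1e-9):
                raise TrialValidationError(
                    "timestamps are not evenly spaced at 0.01 s (100 Hz)"
                )
        if not np.all(np.isin(self.labels, [LABEL_NONFOG, LABEL_FOG, LABEL_PREFOG])):
            raise TrialValidationError("labels contain codes outside {0, 1, 2}")
        if not np.all(
            np.isin(
                self.states,
                [STATE_WALKING, STATE_TURNING, STATE_STANDING, STATE_UNDEFINED],
            )
        ):
            raise TrialValidationError("states contain codes outside {0, 1, 2, 3}")


@dataclass(frozen=True)
class FogEpisode:
    """One annotated freeze episode: [onset_s, end_s) within a trial."""

    onset_s: float
    end_s: float
    trial_id: str

    def __post_init__(self) -> None:
        if not self.end_s > self.onset_s:
            raise TrialValidationError(
                f"episode end {self.end_s} must exceed onset {self.onset_s}"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.onset_s


@dataclass
class SessionManifest:
    """Index of one participant's session: trials and freeze episodes.

    ``is_freezer`` is derived: a participant is a freezer iff at least one
    freeze episode was annotated anywhere in the session.
    """

    participant_id: str
    trial_ids: list[str] = field(default_factory=list)
    episodes: list[FogEpisode] = field(default_factory=list)

    @property
    def is_freezer(self) -> bool:
        return len(self.episodes) > 0

    def episodes_for_trial(self, trial_id: str) -> list[FogEpisode]:
        return [e for e in self.episodes if e.trial_id == trial_id]


def save_trial(trial: Trial, path: str | Path) -> Path:
    """Write a validated trial to an HDF5 container; returns the path."""
    trial.validate()
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with h5py.File(path, "w") as f:
        f.create_dataset("left", data=trial.left_frames.astype(np.float32))
        f.create_dataset("right", data=trial.right_frames.astype(np.float32))
        f.create_dataset("timestamps", data=trial.timestamps)
        f.create_dataset("labels", data=trial.labels.astype(np.uint8))
        f.create_dataset("states", data=trial.states.astype(np.uint8))
        f.attrs["participant_id"] = trial.participant_id
        f.attrs["trial_id"] = trial.trial_id
        f.attrs["condition"] = trial.condition
        f.attrs["sample_rate_hz"] = SAMPLE_RATE_HZ
        f.attrs["cell_pitch_mm"] = CELL_PITCH_MM
    return path


def load_trial(path: str | Path) -> Trial:
    """Read a trial container; validates shape and invariants on load."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        with h5py.File(path, "r") as f:
            required = {"left", "right", "timestamps", "labels", "states"}
            missing = required - set(f.keys())
            if missing:
                raise TrialFormatError(f"{path}: missing datasets {sorted(missing)}")
            trial = Trial(
                trial_id=str(f.attrs["trial_id"]),
                participant_id=str(f.attrs["participant_id"]),
                timestamps=f["timestamps"][:],
                left_frames=f["left"][:].astype(np.float64),
                right_frames=f["right"][:].astype(np.float64),
                labels=f["labels"][:],
                states=f["states"][:],
                condition=str(f.attrs.get("condition", "baseline")),
            )
    except OSError as exc:
        raise OSError(f"cannot read trial container {path}: {exc}") from exc
    return trial


def save_manifest(manifest: SessionManifest, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "participant_id": manifest.participant_id,
        "is_freezer": manifest.is_freezer,
        "trials": list(manifest.trial_ids),
        "episodes": [
            {"trial_id": e.trial_id, "onset_s": e.onset_s, "end_s": e.end_s}
            for e in manifest.episodes
        ],
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def load_manifest(path: str | Path) -> SessionManifest:
    payload = json.loads(Path(path).read_text())
    return SessionManifest(
        participant_id=payload["participant_id"],
        trial_ids=list(payload["trials"]),
        episodes=[
            FogEpisode(e["onset_s"], e["end_s"], e["trial_id"])
            for e in payload["episodes"]
        ],
    )
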