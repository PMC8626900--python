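"""Seeded simulator of labeled plantar-pressure walking sessions.

Real plantar-pressure recordings of people with Parkinson's disease who
freeze are not publicly depositable, so this module generates sessions
with the statistical structure the detection pipeline assumes:

* walking — alternating stance/swing at a configurable cadence, with the
  center of pressure (COP) progressing heel to toe during stance and the
  foot fully unloaded during swing;
* turning — the same stepping pattern with tighter COP excursion and
  asymmetric loading between the feet;
* standing — static bilateral loading with sensor noise only;
* freezing — both feet stay loaded while the COP oscillates with small
  amplitude at a trembling frequency (3–8 Hz), with no anterior
  progression: the pressure signature of trembling-in-place /
  akinetic freezing;
* pre-freeze — a linear ramp-down of step amplitude and cadence over a
  configurable window before each freeze, emulating gait deterioration
  as the person progresses into a freeze.

Each trial opens with a brief standing period containing a single
stomp-like bilateral pressure spike (state ``undefined``), mirroring the
video-synchronization stomp of lab protocols.

Ground-truth labels and activity states are exact by construction, and
identical configuration + seed yields bit-identical output.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass

import numpy as np
import yaml

from .trial_store import (
    GRID_COLS,
    GRID_ROWS,
    LABEL_FOG,
    LABEL_NONFOG,
    SAMPLE_DT_S,
    STATE_STANDING,
    STATE_TURNING,
    STATE_UNDEFINED,
    STATE_WALKING,
    FogEpisode,
    SessionManifest,
    Trial,
)

__all__ = ["SimConfig", "GenerationError", "generate_session", "generate_cohort"]


class GenerationError(ValueError):
    """The requested configuration cannot produce a valid trial."""


#: Default walking-path script: (state, duration_s). The script loosely
#: follows a lab freeze-provoking course: stand up / stomp, walk, turn,
#: walk into a narrow dead end, turn, walk back, stop.
DEFAULT_STATE_SCRIPT: tuple[tuple[str, float], ...] = (
    ("undefined", 1.5),
    ("standing", 1.0),
    ("walking", 8.0),
    ("turning", 2.5),
    ("walking", 6.0),
    ("turning", 2.5),
    ("walking", 8.0),
    ("standing", 1.5),
)

_STATE_CODES = {
    "walking": STATE_WALKING,
    "turning": STATE_TURNING,
    "standing": STATE_STANDING,
    "undefined": STATE_UNDEFINED,
}


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the synthetic cohort.

    Durations are seconds, pressures kPa, frequencies Hz. Episode durations
    are log-normal (right-skewed, like clinically observed freeze
    durations), truncated below at ``episode_min_s``.
    """

    n_participants: int = 11
    freezer_fraction: float = 7 / 11
    trials_per_participant: int = 3
    episode_rate_per_trial: float = 2.0
    episode_duration_mu: float = 0.8  # log-scale mean -> median ~2.2 s
    episode_duration_sigma: float = 0.6
    episode_min_s: float = 0.3
    prefog_deterioration_s: float = 2.0
    cadence_hz: float = 0.9  # full gait cycles per second per foot
    step_load_kpa: float = 900.0  # peak single-foot cell-sum load
    tremble_freq_lo_hz: float = 3.0
    tremble_freq_hi_hz: float = 8.0
    tremble_amp_mm: float = 3.0
    noise_sd_kpa: float = 1.0
    state_script: tuple[tuple[str, float], ...] = DEFAULT_STATE_SCRIPT
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.freezer_fraction <= 1.0:
            raise ValueError("freezer_fraction must be in [0, 1]")
        if self.trials_per_participant < 1 or self.trials_per_participant > 30:
            raise ValueError("trials_per_participant must be in 1..30")
        for name in (
            "episode_duration_sigma",
            "episode_min_s",
            "prefog_deterioration_s",
            "cadence_hz",
            "step_load_kpa",
            "tremble_freq_lo_hz",
            "tremble_freq_hi_hz",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.episode_rate_per_trial < 0:
            raise ValueError("episode_rate_per_trial must be >= 0")
        for state, dur in self.state_script:
            if state not in _STATE_CODES:
                raise ValueError(f"unknown state {state!r} in state_script")
            if dur <= 0:
                raise ValueError("state_script durations must be > 0")

    @property
    def trial_duration_s(self) -> float:
        return float(sum(d for _, d in self.state_script))

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        raw = yaml.safe_load(open(path)) or {}
        if "state_script" in raw:
            raw["state_script"] = tuple(
                (str(s), float(d)) for s, d in raw["state_script"]
            )
        return cls(**raw)


# ---------------------------------------------------------------------------
# frame rendering

_ROWS = np.arange(GRID_ROWS, dtype=np.float64)
_COLS = np.arange(GRID_COLS, dtype=np.float64)

# foot geometry in cell units (row axis: 0 = heel, 59 = toe)
_HEEL_ROW = 10.0
_TOE_ROW = 50.0
_MID_ROW = 30.0
_CENTER_COL = 10.0
_BLOB_SIGMA = 2.5  # cells


def _render_foot(
    load: np.ndarray, row_c: np.ndarray, col_c: np.ndarray, rng: np.random.Generator,
    noise_sd: float,
) -> np.ndarray:
    """Render (T, 60, 21) frames: a Gaussian pressure blob per timestep.

    The blob is centered at (row_c, col_c) and scaled so cells sum to
    ``load``; timesteps with zero load are exactly all-zero (swing phase).
    Sensor noise is added to loaded cells only and clipped at zero.
    """
    T = len(load)
    dr = _ROWS[None, :] - row_c[:, None]  # (T, 60)
    dc = _COLS[None, :] - col_c[:, None]  # (T, 21)
    wr = np.exp(-0.5 * (dr / _BLOB_SIGMA) ** 2)
    wc = np.exp(-0.5 * (dc / _BLOB_SIGMA) ** 2)
    frames = (wr[:, :, None] * wc[:, None, :]).astype(np.float32)  # (T, 60, 21)
    # compact support: drop cells below 2% of the blob peak so sensor noise
    # acts only on genuinely loaded cells
    frames[frames < 0.02] = 0.0
    sums = frames.sum(axis=(1, 2), dtype=np.float64)
    sums[sums == 0] = 1.0
    frames *= (load / sums)[:, None, None].astype(np.float32)
    loaded_cells = frames > 0
    noise = rng.standard_normal(frames.shape, dtype=np.float32) * np.float32(noise_sd)
    frames = np.where(loaded_cells, np.clip(frames + noise, 0.0, None), np.float32(0.0))
    frames[load <= 0] = 0.0
    return frames


# ---------------------------------------------------------------------------
# per-trial kinematic script

def sample_episode_durations(
    rng: np.random.Generator, config: SimConfig, n: int
) -> list[float]:
    """Draw n freeze durations: log-normal, truncated below at the minimum."""
    draws = np.exp(
        rng.normal(config.episode_duration_mu, config.episode_duration_sigma, size=n)
    )
    return [float(max(d, config.episode_min_s)) for d in draws]


def _plan_episodes(
    rng: np.random.Generator,
    config: SimConfig,
    state: np.ndarray,
    durations: list[float],
) -> list[tuple[float, float]]:
    """Place freeze episodes inside walking segments of one trial.

    Episodes are separated by at least ``prefog_deterioration_s`` plus one
    stride so Pre-FOG windows and balancing context do not collide; onset
    and end are snapped to the 100 Hz grid. Episodes that no remaining
    walking segment can host are dropped (long draws in short trials).
    """
    if not durations:
        return []
    walk_mask = state == STATE_WALKING
    # candidate walking segments as (start_s, end_s), trimmed so a freeze
    # never touches the segment edges
    segs = []
    i = 0
    T = len(state)
    while i < T:
        if walk_mask[i]:
            j = i
            while j < T and walk_mask[j]:
                j += 1
            start_s = i * SAMPLE_DT_S + config.prefog_deterioration_s + 0.5
            end_s = j * SAMPLE_DT_S - 0.5
            if end_s > start_s:
                segs.append([start_s, end_s])
            i = j
        else:
            i += 1
    if not segs:
        raise GenerationError("state script has no walking segment to host episodes")

    gap = config.prefog_deterioration_s + 1.0 / config.cadence_hz
    placed: list[tuple[float, float]] = []
    for d in sorted(durations, reverse=True):
        rng.shuffle(segs)
        for seg in segs:
            lo, hi = seg
            if hi - lo >= d:
                onset = lo if hi - lo - d < 1e-9 else float(rng.uniform(lo, hi - d))
                onset = round(onset, 2)
                end = round(onset + d, 2)
                if end <= onset:
                    end = onset + SAMPLE_DT_S
                placed.append((onset, end))
                # split the segment around the episode + guard gap
                segs.remove(seg)
                if onset - gap > lo:
                    segs.append([lo, onset - gap])
                if hi > end + gap:
                    segs.append([end + gap, hi])
                break
    return sorted(placed)


def _simulate_trial(
    rng: np.random.Generator,
    config: SimConfig,
    participant_id: str,
    trial_id: str,
    durations: list[float],
    condition: str,
) -> tuple[Trial, list[FogEpisode]]:
    T = int(round(config.trial_duration_s / SAMPLE_DT_S))
    t = np.arange(T) * SAMPLE_DT_S

    state = np.empty(T, dtype=np.int64)
    pos = 0
    for name, dur in config.state_script:
        n = int(round(dur / SAMPLE_DT_S))
        state[pos : pos + n] = _STATE_CODES[name]
        pos += n
    state[pos:] = _STATE_CODES[config.state_script[-1][0]]

    episodes_s = _plan_episodes(rng, config, state, durations)
    labels = np.full(T, LABEL_NONFOG, dtype=np.int64)
    freeze = np.zeros(T, dtype=bool)
    for onset, end in episodes_s:
        i0, i1 = int(round(onset / SAMPLE_DT_S)), int(round(end / SAMPLE_DT_S))
        labels[i0:i1] = LABEL_FOG
        freeze[i0:i1] = True

    # deterioration envelope: 1 normally, ramping to 0.25 entering a freeze
    envelope = np.ones(T)
    n_pre = int(round(config.prefog_deterioration_s / SAMPLE_DT_S))
    for onset, _ in episodes_s:
        i0 = int(round(onset / SAMPLE_DT_S))
        lo = max(0, i0 - n_pre)
        ramp = np.linspace(1.0, 0.25, i0 - lo, endpoint=False)
        envelope[lo:i0] = np.minimum(envelope[lo:i0], ramp)

    # gait phase advances at cadence, slowed by the deterioration envelope,
    # and pauses entirely during a freeze
    stepping = (
        ((state == STATE_WALKING) | (state == STATE_TURNING)) & ~freeze
    )
    dphase = config.cadence_hz * SAMPLE_DT_S * envelope * stepping
    phase = np.cumsum(dphase)

    load = {"L": np.zeros(T), "R": np.zeros(T)}
    row = {"L": np.full(T, _MID_ROW), "R": np.full(T, _MID_ROW)}
    col = {"L": np.full(T, _CENTER_COL), "R": np.full(T, _CENTER_COL)}

    stance_frac = 0.65
    for foot, offset in (("L", 0.0), ("R", 0.5)):
        ph = (phase + offset) % 1.0
        in_stance = ph < stance_frac
        s = np.where(in_stance, ph / stance_frac, 0.0)  # stance progress 0..1
        # COP excursion shrinks while deteriorating and while turning
        span = (_TOE_ROW - _HEEL_ROW) * envelope
        span = np.where(state == STATE_TURNING, span * 0.45, span)
        r = _MID_ROW + (s - 0.5) * span
        amp = config.step_load_kpa * (0.25 + 0.75 * np.sin(np.pi * s))
        # asymmetric loading while turning (inner vs outer foot)
        asym = 1.0 + (0.3 if foot == "L" else -0.3)
        amp = np.where(state == STATE_TURNING, amp * asym, amp)
        sel = stepping & in_stance
        load[foot][sel] = amp[sel]
        row[foot][sel] = r[sel]
        # slight lateral sway within stance
        col[foot][sel] = _CENTER_COL + np.where(foot == "L", 1.0, -1.0) * np.sin(
            2 * np.pi * ph[sel]
        )

    # standing (and scripted undefined): static bilateral midfoot loading
    static = ((state == STATE_STANDING) | (state == STATE_UNDEFINED)) & ~freeze
    for foot in ("L", "R"):
        load[foot][static] = config.step_load_kpa * 0.5
        row[foot][static] = _MID_ROW
        col[foot][static] = _CENTER_COL

    # stomp spike at the start of the undefined lead-in
    undef = state == STATE_UNDEFINED
    if undef.any():
        i0 = int(np.argmax(undef))
        stomp = slice(i0 + 30, min(i0 + 60, T))
        load["L"][stomp] *= 2.5
        load["R"][stomp] *= 2.5

    # freezing: both feet loaded, COP trembling with no anterior progression
    if freeze.any():
        for onset, end in episodes_s:
            i0, i1 = int(round(onset / SAMPLE_DT_S)), int(round(end / SAMPLE_DT_S))
            f = float(rng.uniform(config.tremble_freq_lo_hz, config.tremble_freq_hi_hz))
            phi = float(rng.uniform(0, 2 * math.pi))
            tt = t[i0:i1]
            osc = np.sin(2 * math.pi * f * tt + phi)
            amp_cells = config.tremble_amp_mm / 5.08
            for foot, sign in (("L", 1.0), ("R", -1.0)):
                row[foot][i0:i1] = _MID_ROW + sign * amp_cells * osc
                col[foot][i0:i1] = _CENTER_COL
                # anti-phase weight shifting between the feet
                load[foot][i0:i1] = config.step_load_kpa * 0.5 * (
                    1.0 + 0.3 * sign * osc
                )

    left = _render_foot(load["L"], row["L"], col["L"], rng, config.noise_sd_kpa)
    right = _render_foot(load["R"], row["R"], col["R"], rng, config.noise_sd_kpa)

    trial = Trial(
        trial_id=trial_id,
        participant_id=participant_id,
        timestamps=t,
        left_frames=left,
        right_frames=right,
        labels=labels,
        states=state,
        condition=condition,
    )
    eps = [FogEpisode(onset, end, trial_id) for onset, end in episodes_s]
    return trial, eps


_CONDITIONS = ("baseline", "verbal", "motor", "dual")


def generate_session(
    config: SimConfig, participant_id: str, is_freezer: bool = True
) -> tuple[SessionManifest, list[Trial]]:
    """Generate one participant's session of labeled trials.

    Freezers receive Poisson(``episode_rate_per_trial``) episodes per trial
    (at least one somewhere in the session); non-freezers none. Drawn
    episodes that cannot fit a walking segment are dropped. Output is a
    deterministic function of (config, participant_id). Raises
    :class:`GenerationError` when the requested mean freeze time exceeds
    the walking time available in a trial.
    """
    walking_s = sum(d for s, d in config.state_script if s == "walking")
    mean_dur = math.exp(
        config.episode_duration_mu + config.episode_duration_sigma**2 / 2
    )
    if is_freezer and config.episode_rate_per_trial * mean_dur > walking_s:
        raise GenerationError(
            "configuration requests more expected freeze time per trial "
            f"({config.episode_rate_per_trial * mean_dur:.1f} s) than the "
            f"trial's walking time ({walking_s:.1f} s)"
        )
    seed = np.random.SeedSequence(
        [config.seed, zlib.crc32(participant_id.encode())]
    )
    rng = np.random.default_rng(seed)
    trials: list[Trial] = []
    episodes: list[FogEpisode] = []
    counts = [
        int(rng.poisson(config.episode_rate_per_trial)) if is_freezer else 0
        for _ in range(config.trials_per_participant)
    ]
    if is_freezer and config.episode_rate_per_trial > 0 and sum(counts) == 0:
        counts[int(rng.integers(len(counts)))] = 1
    planned = [sample_episode_durations(rng, config, n) for n in counts]
    for k, durations in enumerate(planned):
        trial_id = f"{participant_id}_t{k:02d}"
        condition = _CONDITIONS[min(k // 5, len(_CONDITIONS) - 1)]
        trial, eps = _simulate_trial(
            rng, config, participant_id, trial_id, durations, condition
        )
        trials.append(trial)
        episodes.extend(eps)
    if is_freezer and config.episode_rate_per_trial > 0 and not episodes:
        # every drawn episode was dropped for lack of space: retry the last
        # trial with one short episode so the freezer invariant holds
        trial, eps = _simulate_trial(
            rng,
            config,
            participant_id,
            trials[-1].trial_id,
            [min(1.5, walking_s / 4)],
            trials[-1].condition,
        )
        trials[-1] = trial
        episodes.extend(eps)
    manifest = SessionManifest(
        participant_id=participant_id,
        trial_ids=[tr.trial_id for tr in trials],
        episodes=episodes,
    )
    return manifest, trials


def generate_cohort(
    config: SimConfig,
) -> list[tuple[SessionManifest, list[Trial]]]:
    """Generate the full cohort: ceil(freezer_fraction * n) freezers first.

    Participant ids are P01..Pnn; per-participant streams derive
    deterministically from the master seed via the participant id, so the
    cohort is reproducible and any session can be regenerated in isolation.
    """
    if config.n_participants < 2:
        raise ValueError("need at least 2 participants")
    n_freezers = math.ceil(config.freezer_fraction * config.n_participants)
    sessions = []
    for i in range(config.n_participants):
        pid = f"P{i + 1:02d}"
        sessions.append(generate_session(config, pid, is_freezer=i < n_freezers))
    return sessions
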