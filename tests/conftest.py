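import dataclasses

import numpy as np
import pytest

from fogait import SimConfig, Trial, generate_session
from fogait.trial_store import GRID_COLS, GRID_ROWS


def make_trial(
    T: int = 100,
    left=None,
    right=None,
    labels=None,
    states=None,
    trial_id: str = "trial0",
    participant_id: str = "P00",
) -> Trial:
    """Hand-built trial with constant bilateral midfoot loading by default."""
    if left is None:
        left = np.zeros((T, GRID_ROWS, GRID_COLS))
        left[:, 28:33, 8:13] = 10.0
    if right is None:
        right = left.copy()
    return Trial(
        trial_id=trial_id,
        participant_id=participant_id,
        timestamps=np.arange(T) * 0.01,
        left_frames=left,
        right_frames=right,
        labels=np.zeros(T, dtype=int) if labels is None else labels,
        states=np.zeros(T, dtype=int) if states is None else states,
    )


#: Short script / small cohort for fast structural tests.
FAST_SIM = SimConfig(
    n_participants=3,
    freezer_fraction=2 / 3,
    trials_per_participant=1,
    episode_rate_per_trial=1.5,
    episode_duration_mu=0.2,
    episode_duration_sigma=0.4,
    state_script=(
        ("undefined", 1.0),
        ("standing", 1.0),
        ("walking", 7.0),
        ("turning", 2.0),
        ("walking", 7.0),
        ("standing", 1.0),
    ),
    seed=7,
)


@pytest.fixture(scope="session")
def freezer_session():
    """One default-config freezer session, generated once per test session."""
    return generate_session(SimConfig(seed=11), "P01", is_freezer=True)


@pytest.fixture(scope="session")
def fast_cohort():
    from fogait import generate_cohort

    return generate_cohort(FAST_SIM)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
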