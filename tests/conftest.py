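import numpy as np
import pytest

from dualprobe import simulate
from dualprobe.scoring import ParticipantSession, TrialRecord


def make_session(
    participant_id: str,
    n_neg: int,
    n_ben: int,
    n_trials: int = 240,
    interleave: bool = False,
) -> ParticipantSession:
    """Hand-built session with exact outcome counts.

    Negative locus is always left with identities (7, 3): response 7 is a
    negative-locus identification, 3 a benign-locus one, None unidentified.
    With ``interleave`` the outcome types alternate across presentation
    slots (so odd/even halves are as balanced as the counts allow).
    """
    outcomes = ["neg"] * n_neg + ["ben"] * n_ben + ["none"] * (n_trials - n_neg - n_ben)
    if interleave:
        outcomes = [outcomes[i // 2 + (i % 2) * (n_trials // 2)] for i in range(n_trials)]
    trials = [
        TrialRecord(
            participant_id=participant_id,
            video_id=f"v{j // 10 + 1:02d}",
            presentation_index=j + 1,
            negative_locus="left",
            left_identity=7,
            right_identity=3,
            response_identity={"neg": 7, "ben": 3, "none": None}[o],
        )
        for j, o in enumerate(outcomes)
    ]
    return ParticipantSession(participant_id=participant_id, trials=trials)


@pytest.fixture(scope="session")
def calibrated_config() -> simulate.SimulationConfig:
    return simulate.SimulationConfig(
        sigma_theta=simulate.calibrate_from_descriptives(), seed=20260921
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 40-participant calibrated cohort shared across tests."""
    cfg = simulate.SimulationConfig(
        n_participants=40,
        sigma_theta=simulate.calibrate_from_descriptives(),
        seed=7,
    )
    return simulate.simulate_cohort(cfg)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
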