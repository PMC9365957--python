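import pandas as pd
import pytest

from delaychoice.task_design import TrialOption, build_trial_grid


@pytest.fixture(scope="session")
def reward_grid():
    return build_trial_grid("reward")


@pytest.fixture(scope="session")
def loss_grid():
    return build_trial_grid("loss")


@pytest.fixture
def make_trial():
    """Factory for hand-built trials with exact (unrounded) amounts."""

    def _make(
        immediate=2.0,
        ratio=0.5,
        delayed=None,
        condition="reward",
        delay=2.0,
        trial_id=0,
    ):
        return TrialOption(
            trial_id=trial_id,
            condition=condition,
            immediate_amount=immediate,
            ratio=ratio,
            delayed_amount=immediate / ratio if delayed is None else delayed,
            delay=delay,
        )

    return _make


@pytest.fixture
def trial_table_row():
    """Factory for rows of the long trial/choice interchange table."""

    def _row(participant, condition, ratio, choice, trial_id=0, rt_ms=900.0):
        immediate = 1.0
        return {
            "participant": participant,
            "condition": condition,
            "trial_id": trial_id,
            "immediate_amount": immediate,
            "delayed_amount": immediate / ratio,
            "ratio": ratio,
            "delay_weeks": 2.0,
            "choice": choice,
            "rt_ms": rt_ms,
        }

    return _row


@pytest.fixture
def simple_trial_table(trial_table_row):
    """Two participants x one condition x all four ratios, 2 trials per cell."""
    rows = []
    tid = 0
    for participant, pattern in (("sub-01", "immediate"), ("sub-02", "delayed")):
        for ratio in (0.2, 0.4, 0.6, 0.8):
            for _ in range(2):
                rows.append(
                    trial_table_row(participant, "reward", ratio, pattern, tid)
                )
                tid += 1
    return pd.DataFrame(rows)
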