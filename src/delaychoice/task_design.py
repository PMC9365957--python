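"""Trial-grid construction, payout rules and the adaptive response-window staircase.

The experiment crosses eight immediate amounts (EUR 1.00 to 2.75 in 0.25
steps) with four immediate/delayed ratios (0.2, 0.4, 0.6, 0.8), yielding 32
unique intertemporal choices per condition.  The delayed option is always two
weeks away.  The same amounts are used as wins (reward condition) and as
losses (loss condition); losses are subtracted from asymmetric balances
(EUR 8.20 immediate / EUR 10.00 delayed) so that the delayed loss yields the
larger final win in exactly half the trials.

The anticipation phase uses a 1-up/1-down response-window staircase: the
window starts at 300 ms and is multiplied by 1.05 after a slow (or missing)
response and by 0.95 after a fast one, tracking 50 % success.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IMMEDIATE_AMOUNTS",
    "RATIOS",
    "DELAY_WEEKS",
    "DesignError",
    "TrialOption",
    "StaircaseState",
    "PayoutScheme",
    "delayed_amount",
    "build_trial_grid",
    "shuffle_order",
    "tile_grid",
    "staircase_update",
    "simulate_staircase",
    "trial_payout",
    "delayed_advantage_fraction",
    "grid_to_frame",
    "frame_to_grid",
    "write_grid",
    "read_grid",
]

IMMEDIATE_AMOUNTS: tuple[float, ...] = (1.00, 1.25, 1.50, 1.75, 2.00, 2.25, 2.50, 2.75)
RATIOS: tuple[float, ...] = (0.2, 0.4, 0.6, 0.8)

#: Fixed delay of the later option, in weeks.  All discount rates produced by
#: this package are therefore in units of 1/week.
DELAY_WEEKS: float = 2.0

# Trial phase timing (seconds)
DECISION_WINDOW_S = 3.0
CUE_DURATION_S = 6.0
FLASH_DURATION_S = 0.05
FEEDBACK_DURATION_S = 1.5
ISI_RANGE_S = (1.0, 2.0)
ITI_RANGE_S = (1.5, 5.0)

STAIRCASE_START_MS = 300.0
STAIRCASE_UP = 1.05    # applied after a slow/missing response
STAIRCASE_DOWN = 0.95  # applied after a fast response

CONDITIONS = ("reward", "loss")


class DesignError(ValueError):
    """Invalid task-design input (amounts, ratios, condition)."""


@dataclass(frozen=True)
class TrialOption:
    """One intertemporal choice: a smaller immediate vs. a larger delayed amount.

    Amounts are stored as positive magnitudes in EUR regardless of condition;
    the sign convention (losses negative) is applied by the valuation model.
    """

    trial_id: int
    condition: str
    immediate_amount: float
    ratio: float
    delayed_amount: float
    delay: float = DELAY_WEEKS

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise DesignError(f"unknown condition {self.condition!r}")
        if self.delayed_amount < self.immediate_amount:
            raise DesignError("delayed amount must be >= immediate amount")


@dataclass(frozen=True)
class StaircaseState:
    """Current response window (ms) plus the (rt, success) history."""

    threshold: float = STAIRCASE_START_MS
    history: tuple = ()

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise DesignError("staircase threshold must be positive")


@dataclass(frozen=True)
class PayoutScheme:
    """Outcome rules: failed wins become EUR 0, failed losses are doubled.

    In the loss condition the chosen loss is subtracted from a starting
    balance of EUR 8.20 (immediate choices) or EUR 10.00 (delayed choices);
    the participant keeps the remainder.
    """

    reward_failure_value: float = 0.0
    loss_failure_multiplier: float = 2.0
    balance_immediate: float = 8.20
    balance_delayed: float = 10.00


def delayed_amount(immediate: float, ratio: float, rounding: str = "floor") -> float:
    """Delayed amount for a given immediate amount and immediate/delayed ratio.

    The nominal value immediate/ratio is rounded to whole cents; the default
    convention is to round down (e.g. 1.00/0.6 -> 1.66).

    Parameters
    ----------
    immediate : positive amount in EUR.
    ratio : immediate/delayed ratio, strictly between 0 and 1.
    rounding : "floor" (default) or "nearest".
    """
    if immediate <= 0:
        raise DesignError("immediate amount must be positive")
    if not 0 < ratio < 1:
        raise DesignError("ratio must lie strictly between 0 and 1")
    cents = immediate * 100.0 / ratio
    # guard against 166.99999... artefacts of binary floats before flooring
    cents = cents + 1e-9
    if rounding == "floor":
        return math.floor(cents) / 100.0
    if rounding == "nearest":
        return round(cents) / 100.0
    raise DesignError(f"unknown rounding mode {rounding!r}")


def build_trial_grid(condition: str, rounding: str = "floor") -> list[TrialOption]:
    """All 32 (immediate amount x ratio) trial options for one condition.

    Ordering is deterministic by (immediate_amount, ratio); presentation-order
    shuffling is a separate, seeded step (:func:`shuffle_order`).
    """
    if condition not in CONDITIONS:
        raise DesignError(f"unknown condition {condition!r}")
    grid = []
    tid = 0
    for amount in IMMEDIATE_AMOUNTS:
        for ratio in RATIOS:
            grid.append(
                TrialOption(
                    trial_id=tid,
                    condition=condition,
                    immediate_amount=amount,
                    ratio=ratio,
                    delayed_amount=delayed_amount(amount, ratio, rounding),
                )
            )
            tid += 1
    return grid


def shuffle_order(n_trials: int, seed: int) -> np.ndarray:
    """Seeded presentation-order permutation.

    The same permutation is reused for a participant's reward and loss
    sessions, which are identical except for valence.
    """
    return np.random.default_rng(seed).permutation(n_trials)


def tile_grid(grid: Sequence[TrialOption], k: int) -> list[TrialOption]:
    """Repeat a grid k times with running trial ids (for longer sessions)."""
    out = []
    tid = 0
    for _ in range(k):
        for t in grid:
            out.append(replace(t, trial_id=tid))
            tid += 1
    return out


def staircase_update(
    state: StaircaseState,
    rt_ms: Optional[float],
    up: float = STAIRCASE_UP,
    down: float = STAIRCASE_DOWN,
    mode: str = "multiplicative",
) -> StaircaseState:
    """Apply one 1-up/1-down step of the adaptive response window.

    A response is a success iff it arrives within the current window
    (rt <= threshold); a missing response counts as slow.  After a success the
    window shrinks by 5 %, after a failure it grows by 5 %.  ``mode`` selects
    the multiplicative convention (default) or an additive variant stepping
    by 5 % of the starting window.
    """
    success = (
        rt_ms is not None and not (isinstance(rt_ms, float) and math.isnan(rt_ms))
        and rt_ms <= state.threshold
    )
    if mode == "multiplicative":
        new_threshold = state.threshold * (down if success else up)
    elif mode == "additive":
        step = (1.0 - down) * STAIRCASE_START_MS
        new_threshold = state.threshold + (-step if success else step)
        new_threshold = max(new_threshold, 1e-9)
    else:
        raise DesignError(f"unknown staircase mode {mode!r}")
    return StaircaseState(
        threshold=new_threshold, history=state.history + ((rt_ms, success),)
    )


def simulate_staircase(
    n_trials: int,
    seed: int,
    rt_median_ms: float = 300.0,
    rt_log_sd: float = 0.2,
    burn_in: int = 500,
    start_ms: float = STAIRCASE_START_MS,
) -> float:
    """Long-run success fraction of the staircase against a log-normal agent.

    Simulates ``n_trials`` responses with i.i.d. log-normal reaction times
    (median ``rt_median_ms``, log-scale SD ``rt_log_sd``), runs the 1-up/1-down
    +/-5 % rule, and returns the success fraction after discarding the first
    ``burn_in`` trials.  The equal-step rule converges to 50 % success.
    """
    if n_trials <= burn_in:
        raise DesignError("n_trials must exceed burn_in")
    rng = np.random.default_rng(seed)
    rts = rt_median_ms * np.exp(rng.normal(0.0, rt_log_sd, size=n_trials))
    threshold = start_ms
    successes = np.empty(n_trials, dtype=bool)
    for i, rt in enumerate(rts):
        ok = rt <= threshold
        successes[i] = ok
        threshold *= STAIRCASE_DOWN if ok else STAIRCASE_UP
    return float(successes[burn_in:].mean())


def trial_payout(
    trial: TrialOption,
    choice: str,
    success: bool,
    scheme: PayoutScheme | None = None,
) -> float:
    """Final amount won on a trial given the choice and MID success.

    Reward condition: the chosen amount if the speeded response succeeded,
    otherwise the failure value (EUR 0).  Loss condition: the relevant balance
    minus the chosen loss, doubled on failure.
    """
    scheme = scheme or PayoutScheme()
    if choice not in ("immediate", "delayed"):
        raise DesignError(f"invalid choice {choice!r}")
    amount = trial.immediate_amount if choice == "immediate" else trial.delayed_amount
    if trial.condition == "reward":
        return amount if success else scheme.reward_failure_value
    balance = (
        scheme.balance_immediate if choice == "immediate" else scheme.balance_delayed
    )
    loss = amount if success else scheme.loss_failure_multiplier * amount
    return balance - loss


def delayed_advantage_fraction(
    grid: Iterable[TrialOption], scheme: PayoutScheme | None = None
) -> float:
    """Fraction of loss trials where the delayed choice yields the higher win.

    Assumes MID success on both options; this is the design property the
    asymmetric balances were chosen for (0.50 on the full 32-trial grid).
    """
    scheme = scheme or PayoutScheme()
    grid = list(grid)
    if not grid:
        raise DesignError("empty grid")
    if any(t.condition != "loss" for t in grid):
        raise DesignError("delayed_advantage_fraction applies to loss grids only")
    wins_delayed = np.array([scheme.balance_delayed - t.delayed_amount for t in grid])
    wins_immediate = np.array(
        [scheme.balance_immediate - t.immediate_amount for t in grid]
    )
    return float(np.mean(wins_delayed > wins_immediate))


# ---------------------------------------------------------------------------
# tabular round trip

GRID_COLUMNS = [
    "trial_id",
    "condition",
    "immediate_amount",
    "ratio",
    "delayed_amount",
    "delay_weeks",
]


def grid_to_frame(grid: Sequence[TrialOption]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trial_id": [t.trial_id for t in grid],
            "condition": [t.condition for t in grid],
            "immediate_amount": [t.immediate_amount for t in grid],
            "ratio": [t.ratio for t in grid],
            "delayed_amount": [t.delayed_amount for t in grid],
            "delay_weeks": [t.delay for t in grid],
        }
    )


def frame_to_grid(df: pd.DataFrame) -> list[TrialOption]:
    return [
        TrialOption(
            trial_id=int(row.trial_id),
            condition=str(row.condition),
            immediate_amount=float(row.immediate_amount),
            ratio=float(row.ratio),
            delayed_amount=float(row.delayed_amount),
            delay=float(row.delay_weeks),
        )
        for row in df.itertuples(index=False)
    ]


def write_grid(grid: Sequence[TrialOption], path) -> None:
    grid_to_frame(grid).to_csv(path, sep="\t", index=False)


def read_grid(path) -> list[TrialOption]:
    return frame_to_grid(pd.read_csv(path, sep="\t"))
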