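"""BIDS-style event tables for the task's GLM regressors.

Builds, per session, the regressors of interest (decision phase with RT
duration, anticipation cue with fixed 6 s duration), the regressors of
non-interest (button presses, flash, feedback), missed-decision dummy events,
subjective-value parametric modulators and choice-split regressors.  GLM
estimation itself is out of scope; the output is a plain events.tsv any
neuroimaging stack can consume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .task_design import CUE_DURATION_S, DECISION_WINDOW_S, FEEDBACK_DURATION_S, FLASH_DURATION_S

__all__ = [
    "EventsError",
    "EVENT_TYPES",
    "build_phase_events",
    "attach_sv_modulators",
    "split_by_choice",
    "ChoiceSplitResult",
    "write_events",
    "read_events",
]

EVENT_TYPES = (
    "decision",
    "anticipation",
    "button_decision",
    "flash",
    "button_flash",
    "feedback",
    "missed_dummy",
)

_META_COLS = [
    "trial_id",
    "condition",
    "choice",
    "immediate_amount",
    "delayed_amount",
    "ratio",
    "delay_weeks",
]


class EventsError(ValueError):
    """Malformed session timeline or missing dependency (e.g. kappa)."""


def _finite(x) -> bool:
    return x is not None and np.isfinite(x)


def build_phase_events(session) -> pd.DataFrame:
    """Event table (onset, duration, trial_type, trial metadata) for a session.

    Regressors of interest: ``decision`` (duration = that trial's reaction
    time) and ``anticipation`` (fixed 6 s cue).  Non-interest events: decision
    button press, flash, post-flash button press, feedback.  Trials without a
    decision are routed to a ``missed_dummy`` event covering the decision
    window; they contribute no anticipation-phase events because no option was
    chosen and cued.
    """
    rows = []
    for k, trial in enumerate(session.trials):
        meta = {
            "trial_id": trial.trial_id,
            "condition": session.condition,
            "choice": session.choices[k] if session.choices[k] else np.nan,
            "immediate_amount": trial.immediate_amount,
            "delayed_amount": trial.delayed_amount,
            "ratio": trial.ratio,
            "delay_weeks": trial.delay,
        }
        onset = session.decision_onset_s[k]
        if not _finite(onset) or onset < 0:
            raise EventsError(f"invalid decision onset on trial {trial.trial_id}")
        rt_ms = session.decision_rt_ms[k]
        missed = session.choices[k] not in ("immediate", "delayed")
        if missed:
            rows.append(
                {"onset": onset, "duration": DECISION_WINDOW_S,
                 "trial_type": "missed_dummy", **meta}
            )
            continue
        rt_s = float(rt_ms) / 1000.0
        rows.append(
            {"onset": onset, "duration": rt_s, "trial_type": "decision", **meta}
        )
        rows.append(
            {"onset": onset + rt_s, "duration": 0.0,
             "trial_type": "button_decision", **meta}
        )
        a = session.anticipation_onset_s[k]
        f = session.flash_onset_s[k]
        fb = session.feedback_onset_s[k]
        if not (_finite(a) and _finite(f) and _finite(fb)):
            raise EventsError(f"missing anticipation timing on trial {trial.trial_id}")
        rows.append(
            {"onset": a, "duration": CUE_DURATION_S,
             "trial_type": "anticipation", **meta}
        )
        rows.append(
            {"onset": f, "duration": FLASH_DURATION_S, "trial_type": "flash", **meta}
        )
        mid_rt = session.mid_rt_ms[k]
        if _finite(mid_rt):
            rows.append(
                {"onset": f + FLASH_DURATION_S + float(mid_rt) / 1000.0,
                 "duration": 0.0, "trial_type": "button_flash", **meta}
            )
        rows.append(
            {"onset": fb, "duration": FEEDBACK_DURATION_S,
             "trial_type": "feedback", **meta}
        )
    df = pd.DataFrame(rows).sort_values("onset", kind="stable").reset_index(drop=True)
    if not df["onset"].is_monotonic_increasing:
        raise EventsError("event onsets are not increasing")
    return df


def _signed_values(df: pd.DataFrame, kappa: float) -> tuple[np.ndarray, np.ndarray]:
    sign = np.where(df["condition"] == "loss", -1.0, 1.0)
    v_imm = sign * df["immediate_amount"].to_numpy(float)
    v_del = (
        sign
        * df["delayed_amount"].to_numpy(float)
        / (1.0 + kappa * df["delay_weeks"].to_numpy(float))
    )
    return v_imm, v_del


def attach_sv_modulators(
    events: pd.DataFrame, kappa: Optional[float], model: str = "decision_diff"
) -> pd.DataFrame:
    """Attach subjective-value parametric modulators to an event table.

    model="decision_diff"
        adds ``sv_diff`` = |V(immediate) - V(delayed)| on decision events
        (small values mark difficult trials near indifference).
    model="anticipation_sv"
        adds ``sv`` = subjective value of the chosen, cued option on
        anticipation events; absolute-valued in the loss condition so that a
        larger value means a larger prospective loss.

    Both raw and within-session mean-centered (``*_centered``) columns are
    emitted; rows of other event types carry NaN.
    """
    if kappa is None or not np.isfinite(kappa):
        raise EventsError("a fitted kappa is required to compute subjective values")
    if kappa < 0:
        raise EventsError("kappa must be non-negative")
    out = events.copy()
    v_imm, v_del = _signed_values(out, kappa)
    if model == "decision_diff":
        mask = out["trial_type"] == "decision"
        col = "sv_diff"
        values = np.abs(v_imm - v_del)
    elif model == "anticipation_sv":
        mask = out["trial_type"] == "anticipation"
        col = "sv"
        chosen = np.where(out["choice"] == "immediate", v_imm, v_del)
        values = np.where(out["condition"] == "loss", np.abs(chosen), chosen)
    else:
        raise EventsError(f"unknown modulator model {model!r}")
    out[col] = np.where(mask, values, np.nan)
    centered = out[col] - out.loc[mask, col].mean()
    out[f"{col}_centered"] = np.where(mask, centered, np.nan)
    return out


@dataclass(frozen=True)
class ChoiceSplitResult:
    """Choice-split events, or an exclusion flag for low-variance sessions."""

    events: Optional[pd.DataFrame]
    excluded: bool
    n_discounted: int


def split_by_choice(events: pd.DataFrame, min_discounted: int = 6) -> ChoiceSplitResult:
    """Split decision/anticipation regressors by immediate vs. delayed choice.

    Sessions with fewer than ``min_discounted`` discounted choices (the 20 %
    criterion: 6 of 32 trials) are flagged excluded and return no table.
    """
    decision = events[events["trial_type"] == "decision"]
    condition = events["condition"].iloc[0]
    discounted_label = "immediate" if condition == "reward" else "delayed"
    n_discounted = int((decision["choice"] == discounted_label).sum())
    if n_discounted < min_discounted:
        return ChoiceSplitResult(events=None, excluded=True, n_discounted=n_discounted)
    out = events.copy()
    split_mask = out["trial_type"].isin(["decision", "anticipation"])
    out["trial_type"] = np.where(
        split_mask, out["trial_type"] + "_" + out["choice"].astype(str), out["trial_type"]
    )
    return ChoiceSplitResult(events=out, excluded=False, n_discounted=n_discounted)


def write_events(events: pd.DataFrame, path) -> None:
    """Write a BIDS-style events.tsv (4-decimal numeric precision, n/a for NaN).

    Numeric columns are rounded before writing so that a write/read cycle is
    an exact round trip at file precision.
    """
    out = events.copy()
    for col in out.columns:
        if pd.api.types.is_float_dtype(out[col]):
            out[col] = out[col].round(4)
    out.to_csv(path, sep="\t", index=False, na_rep="n/a", float_format="%.4f")


def read_events(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["n/a"])
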