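"""Hyperbolic delay-discounting model with softmax choice rule and constrained MLE.

Model
-----
The subjective value of the delayed option declines hyperbolically with the
delay D:

    V(a2) = r2 / (1 + kappa * D),        V(a1) = r1        (immediate, D = 0)

where kappa >= 0 is the individual discount rate (per delay unit; weeks in
this package) and r1, r2 are the signed outcomes (losses enter as negative
amounts, so one formula serves both conditions).  Choices follow an
inverse-temperature softmax

    p(a_i) = exp(V(a_i) / beta) / sum_j exp(V(a_j) / beta)

with beta in [eps, 1]: small beta approaches deterministic value
maximisation, large beta approaches random choice.  (kappa, beta) are
estimated per participant and condition by constrained maximum likelihood
with multi-start bounded optimisation.

The "discounted" choice is the immediate option for rewards and the delayed
option for losses; higher kappa makes it more likely in both conditions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .task_design import DELAY_WEEKS, TrialOption, build_trial_grid

__all__ = [
    "BETA_FLOOR",
    "KAPPA_MAX",
    "ModelError",
    "NoDataError",
    "SubjectiveValue",
    "DiscountParams",
    "subjective_value",
    "choice_probability",
    "indifference_kappa",
    "sv_difference",
    "negative_log_likelihood",
    "predict_discount_frequency",
    "HyperbolicDiscounting",
    "DiscountingResults",
    "fit_mle",
    "fit_cohort",
]

#: Lower bound on the softmax noise parameter, keeps 1/beta finite.
BETA_FLOOR = 1e-4
#: Upper bound on the discount rate; far above any trial's indifference rate
#: (the steepest ratio, 0.2, is indifferent at kappa = 2 per week).
KAPPA_MAX = 10.0
#: Per-trial likelihood floor (log scale).
_LOG_LIK_FLOOR = np.log(1e-300)
#: Boundary-detection tolerance for fitted parameters.
_BOUNDARY_TOL = 1e-3

MISSING_CHOICES = {None, "", "missing", "n/a", "nan"}


class ModelError(ValueError):
    """Invalid model input or constraint violation."""


class NoDataError(ModelError):
    """No usable (non-missing) choices."""


@dataclass(frozen=True)
class DiscountParams:
    """A (kappa, beta) pair for one participant and condition."""

    kappa: float
    beta: float

    def __post_init__(self) -> None:
        if self.kappa < 0:
            raise ModelError("kappa must be non-negative")
        if not 0 <= self.beta <= 1:
            raise ModelError("beta must lie in [0, 1]")


@dataclass(frozen=True)
class SubjectiveValue:
    """Signed subjective value plus its magnitude (used for loss reporting)."""

    value: float
    abs_value: float


def subjective_value(outcome: float, delay: float, kappa: float) -> SubjectiveValue:
    """Hyperbolically discounted value of a signed outcome at a given delay.

    Immediate options use delay = 0 and are therefore worth their face value.
    Losses (negative outcomes) discount toward zero, i.e. become less aversive
    with delay.
    """
    if kappa < 0:
        raise ModelError("kappa must be non-negative")
    if delay < 0:
        raise ModelError("delay must be non-negative")
    v = outcome / (1.0 + kappa * delay)
    return SubjectiveValue(value=v, abs_value=abs(v))


def _clamped_beta(beta: float) -> float:
    if beta < BETA_FLOOR:
        warnings.warn(
            f"beta={beta} below floor {BETA_FLOOR}; clamping", RuntimeWarning,
            stacklevel=3,
        )
        return BETA_FLOOR
    if beta > 1.0:
        raise ModelError("beta must not exceed 1")
    return beta


def choice_probability(v_chosen: float, v_other: float, beta: float) -> float:
    """Softmax probability of the option with value ``v_chosen``.

    Computed through the logistic of the value difference scaled by 1/beta,
    which is overflow-safe and shift-invariant by construction.
    """
    beta = _clamped_beta(beta)
    x = (v_chosen - v_other) / beta
    # logistic with clipped argument; exp() overflows past ~709
    x = np.clip(x, -709.0, 709.0)
    return float(1.0 / (1.0 + np.exp(-x)))


def indifference_kappa(ratio: float, delay: float = DELAY_WEEKS) -> float:
    """Discount rate at which the immediate and delayed options have equal value."""
    return (1.0 / ratio - 1.0) / delay


def sv_difference(trial: TrialOption, kappa: float, signed_sign: float = None) -> float:
    """|V(immediate) - V(delayed)| for one trial; an index of decision ease.

    Values near zero mark difficult trials close to the indifference point.
    Losses are handled through the signed-outcome convention.
    """
    if kappa < 0:
        raise ModelError("kappa must be non-negative")
    sign = -1.0 if trial.condition == "loss" else 1.0
    v_imm = sign * trial.immediate_amount
    v_del = sign * trial.delayed_amount / (1.0 + kappa * trial.delay)
    return abs(v_imm - v_del)


def _signed_arrays(trials: Sequence[TrialOption]):
    sign = np.array([-1.0 if t.condition == "loss" else 1.0 for t in trials])
    r_imm = sign * np.array([t.immediate_amount for t in trials])
    r_del = sign * np.array([t.delayed_amount for t in trials])
    delay = np.array([t.delay for t in trials])
    return r_imm, r_del, delay


def _choice_mask(choices: Sequence) -> tuple[np.ndarray, np.ndarray]:
    """(valid mask, chose_delayed indicator over valid trials)."""
    valid = []
    delayed = []
    for c in choices:
        if c is None or (isinstance(c, float) and np.isnan(c)):
            valid.append(False)
            delayed.append(False)
            continue
        s = str(c).strip().lower()
        if s in MISSING_CHOICES:
            valid.append(False)
            delayed.append(False)
        elif s in ("immediate", "delayed"):
            valid.append(True)
            delayed.append(s == "delayed")
        else:
            raise ModelError(f"unrecognised choice label {c!r}")
    return np.asarray(valid), np.asarray(delayed)


def _nll_core(
    kappa: float,
    beta: float,
    r_imm: np.ndarray,
    r_del: np.ndarray,
    delay: np.ndarray,
    chose_delayed: np.ndarray,
) -> float:
    v_imm = r_imm
    v_del = r_del / (1.0 + kappa * delay)
    # log p(delayed) = -log(1 + exp(-(v_del - v_imm)/beta)), stable form
    x = (v_del - v_imm) / beta
    x = np.clip(x, -709.0, 709.0)
    logp_del = -np.logaddexp(0.0, -x)
    logp_imm = -np.logaddexp(0.0, x)
    logp = np.where(chose_delayed, logp_del, logp_imm)
    logp = np.maximum(logp, _LOG_LIK_FLOOR)
    return float(-np.sum(logp))


def negative_log_likelihood(
    params: DiscountParams | tuple,
    trials: Sequence[TrialOption],
    choices: Sequence,
) -> float:
    """-sum log p(chosen) over trials with a recorded choice.

    Missing choices (no response within the decision window) are skipped, as
    in the behavioural analysis; a session with no recorded choice at all
    raises :class:`NoDataError`.
    """
    if isinstance(params, DiscountParams):
        kappa, beta = params.kappa, params.beta
    else:
        kappa, beta = params
    if kappa < 0:
        raise ModelError("kappa must be non-negative")
    beta = _clamped_beta(beta)
    if len(trials) != len(choices):
        raise ModelError("trials and choices must be aligned")
    valid, delayed = _choice_mask(choices)
    if not valid.any():
        raise NoDataError("all choices missing")
    r_imm, r_del, delay = _signed_arrays(trials)
    return _nll_core(
        kappa, beta, r_imm[valid], r_del[valid], delay[valid], delayed[valid]
    )


def _discounted_probability(
    grid: Sequence[TrialOption], kappa: float, beta: float
) -> np.ndarray:
    """Per-trial model probability of the discounted choice."""
    beta = _clamped_beta(beta)
    r_imm, r_del, delay = _signed_arrays(grid)
    v_imm = r_imm
    v_del = r_del / (1.0 + kappa * delay)
    x = (v_del - v_imm) / beta
    x = np.clip(x, -709.0, 709.0)
    p_delayed = 1.0 / (1.0 + np.exp(-x))
    is_loss = np.array([t.condition == "loss" for t in grid])
    return np.where(is_loss, p_delayed, 1.0 - p_delayed)


def predict_discount_frequency(
    params: DiscountParams | tuple, grid: Sequence[TrialOption]
) -> pd.Series:
    """Mean model probability of the discounted choice, per ratio.

    The discounted choice is immediate in the reward condition and delayed in
    the loss condition.
    """
    if isinstance(params, DiscountParams):
        kappa, beta = params.kappa, params.beta
    else:
        kappa, beta = params
    p = _discounted_probability(grid, kappa, beta)
    ratios = np.array([t.ratio for t in grid])
    return pd.Series(p).groupby(ratios).mean().rename("p_discounted")


class HyperbolicDiscounting:
    """Hyperbolic discounting model for one participant-condition session.

    Parameters
    ----------
    trials : sequence of TrialOption
        The presented choices.
    choices : sequence
        "immediate", "delayed", or a missing marker (None/NaN/"missing")
        per trial.
    kappa_max, beta_floor : optimisation bounds for (kappa, beta).

    Examples
    --------
    >>> grid = build_trial_grid("reward")
    >>> model = HyperbolicDiscounting(grid, ["delayed"] * 32)
    >>> res = model.fit(seed=0)
    >>> res.kappa  # doctest: +SKIP
    0.0
    """

    def __init__(
        self,
        trials: Sequence[TrialOption],
        choices: Sequence,
        kappa_max: float = KAPPA_MAX,
        beta_floor: float = BETA_FLOOR,
    ):
        if len(trials) != len(choices):
            raise ModelError("trials and choices must be aligned")
        self.trials = list(trials)
        self.choices = list(choices)
        self.kappa_max = float(kappa_max)
        self.beta_floor = float(beta_floor)
        valid, delayed = _choice_mask(self.choices)
        if not valid.any():
            raise NoDataError("all choices missing")
        r_imm, r_del, delay = _signed_arrays(self.trials)
        self._r_imm = r_imm[valid]
        self._r_del = r_del[valid]
        self._delay = delay[valid]
        self._chose_delayed = delayed[valid]
        self.n_trials_used = int(valid.sum())

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        condition: Optional[str] = None,
        delay: float = DELAY_WEEKS,
        **kwargs,
    ) -> "HyperbolicDiscounting":
        """Build a model from a long trial/choice table.

        Expected columns: immediate_amount, delayed_amount, ratio, choice and
        (unless ``condition`` is given) condition.  A delay_weeks column is
        used when present.
        """
        if condition is not None:
            df = df[df["condition"] == condition]
        trials = []
        for i, row in enumerate(df.itertuples(index=False)):
            trials.append(
                TrialOption(
                    trial_id=int(getattr(row, "trial_id", i)),
                    condition=str(
                        condition if condition is not None else row.condition
                    ),
                    immediate_amount=float(row.immediate_amount),
                    ratio=float(row.ratio),
                    delayed_amount=float(row.delayed_amount),
                    delay=float(getattr(row, "delay_weeks", delay)),
                )
            )
        return cls(trials, list(df["choice"]), **kwargs)

    def nloglike(self, params) -> float:
        """Negative log-likelihood at (kappa, beta), over non-missing trials."""
        kappa, beta = float(params[0]), float(params[1])
        kappa = min(max(kappa, 0.0), self.kappa_max)
        beta = min(max(beta, self.beta_floor), 1.0)
        return _nll_core(
            kappa, beta, self._r_imm, self._r_del, self._delay, self._chose_delayed
        )

    def fit(self, n_starts: int = 10, seed: int = 0) -> "DiscountingResults":
        """Constrained maximum-likelihood fit with seeded multi-start.

        Runs ``n_starts`` L-BFGS-B optimisations from log-uniform kappa and
        uniform beta starting points and keeps the best.  The two-parameter
        likelihood on 32 binary choices can be multi-modal for extreme
        choosers, hence the restarts.
        """
        if n_starts < 1:
            raise ModelError("n_starts must be >= 1")
        rng = np.random.default_rng(seed)
        bounds = [(0.0, self.kappa_max), (self.beta_floor, 1.0)]
        starts = [(0.3, 0.3)]  # population-plausible anchor start
        log_lo, log_hi = np.log(1e-3), np.log(self.kappa_max)
        for _ in range(n_starts - 1):
            starts.append(
                (
                    float(np.exp(rng.uniform(log_lo, log_hi))),
                    float(rng.uniform(self.beta_floor, 1.0)),
                )
            )
        best = None
        any_success = False
        for x0 in starts[:n_starts]:
            res = optimize.minimize(
                self.nloglike, x0=np.asarray(x0), method="L-BFGS-B", bounds=bounds
            )
            any_success = any_success or bool(res.success)
            if best is None or res.fun < best.fun:
                best = res
        if best is None or not np.isfinite(best.fun):
            raise ModelError("optimizer failed on all starts")
        kappa, beta = float(best.x[0]), float(best.x[1])
        boundary = (
            kappa <= _BOUNDARY_TOL
            or kappa >= self.kappa_max - _BOUNDARY_TOL
            or beta <= self.beta_floor + _BOUNDARY_TOL
            or beta >= 1.0 - _BOUNDARY_TOL
        )
        return DiscountingResults(
            model=self,
            params=DiscountParams(kappa=max(kappa, 0.0), beta=beta),
            neg_log_likelihood=float(best.fun),
            converged=any_success,
            n_starts=n_starts,
            boundary_flag=bool(boundary),
        )


@dataclass
class DiscountingResults:
    """MLE results for one session; produced by :meth:`HyperbolicDiscounting.fit`."""

    model: HyperbolicDiscounting
    params: DiscountParams
    neg_log_likelihood: float
    converged: bool
    n_starts: int
    boundary_flag: bool

    @property
    def kappa(self) -> float:
        return self.params.kappa

    @property
    def beta(self) -> float:
        return self.params.beta

    @property
    def n_trials_used(self) -> int:
        return self.model.n_trials_used

    def predict(self, grid: Optional[Sequence[TrialOption]] = None) -> np.ndarray:
        """Per-trial probability of the discounted choice under the fit."""
        grid = self.model.trials if grid is None else grid
        return _discounted_probability(grid, self.kappa, self.beta)

    def predict_discount_frequency(
        self, grid: Optional[Sequence[TrialOption]] = None
    ) -> pd.Series:
        grid = self.model.trials if grid is None else grid
        return predict_discount_frequency(self.params, grid)

    def sv_difference(self, trial: TrialOption) -> float:
        return sv_difference(trial, self.kappa)

    def summary(self) -> str:
        lines = [
            "Hyperbolic discounting MLE",
            "==========================",
            f"kappa (1/week)      {self.kappa:10.4f}",
            f"beta                {self.beta:10.4f}",
            f"neg. log-likelihood {self.neg_log_likelihood:10.4f} nats",
            f"trials used         {self.n_trials_used:10d}",
            f"restarts            {self.n_starts:10d}",
            f"converged           {str(self.converged):>10}",
            f"boundary solution   {str(self.boundary_flag):>10}",
        ]
        return "\n".join(lines)


def fit_mle(
    trials: Sequence[TrialOption],
    choices: Sequence,
    n_starts: int = 10,
    seed: int = 0,
    **kwargs,
) -> DiscountingResults:
    """Convenience wrapper: build a :class:`HyperbolicDiscounting` and fit it."""
    return HyperbolicDiscounting(trials, choices, **kwargs).fit(
        n_starts=n_starts, seed=seed
    )


def fit_cohort(
    trial_table: pd.DataFrame, n_starts: int = 10, seed: int = 0
) -> pd.DataFrame:
    """Fit every participant-condition session in a long trial/choice table.

    Returns one row per (participant, condition) with columns kappa, beta,
    nll, n_trials, converged, boundary_flag.  Per-session fit seeds are
    derived deterministically from ``seed``.
    """
    rows = []
    ss = np.random.SeedSequence(seed)
    keys = sorted(
        trial_table.groupby(["participant", "condition"]).groups.keys()
    )
    child_seeds = ss.spawn(len(keys))
    for (participant, condition), child in zip(keys, child_seeds):
        sub = trial_table[
            (trial_table["participant"] == participant)
            & (trial_table["condition"] == condition)
        ]
        model = HyperbolicDiscounting.from_dataframe(sub, condition=condition)
        res = model.fit(n_starts=n_starts, seed=int(child.generate_state(1)[0] % (2**31)))
        rows.append(
            {
                "participant": participant,
                "condition": condition,
                "kappa": res.kappa,
                "beta": res.beta,
                "nll": res.neg_log_likelihood,
                "n_trials": res.n_trials_used,
                "converged": res.converged,
                "boundary_flag": res.boundary_flag,
            }
        )
    return pd.DataFrame(rows)
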