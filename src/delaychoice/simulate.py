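"""Synthetic cohorts and sessions with the statistical structure the analysis assumes.

The generator replicates the study conditions: 30 participants, two sessions
(reward and loss) of 32 trials each, per-participant discount rates kappa
drawn from a correlated bivariate log-normal matched to the observed moments
(reward 0.33 +/- 0.48, loss 0.30 +/- 0.32, cross-condition r = 0.56), softmax
noise beta from truncated normals (0.38 +/- 0.41 and 0.39 +/- 0.39 on [eps, 1]),
about 1.56 % missed decisions, decision reaction times following the fitted
linear mixed-effects structure (intercept ~1043 ms, ratio slope ~242 ms),
speeded MID responses around 240 ms tracked by the adaptive staircase, and
BIS-15 subscale scores.

A single global seed fans out via ``numpy.random.SeedSequence`` substreams so
any participant's session is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .task_design import (
    CUE_DURATION_S,
    DECISION_WINDOW_S,
    FEEDBACK_DURATION_S,
    FLASH_DURATION_S,
    ISI_RANGE_S,
    ITI_RANGE_S,
    STAIRCASE_START_MS,
    PayoutScheme,
    StaircaseState,
    TrialOption,
    build_trial_grid,
    shuffle_order,
    staircase_update,
    trial_payout,
)
from .model import BETA_FLOOR, DiscountParams, _discounted_probability

__all__ = [
    "SpecError",
    "RTDecisionSpec",
    "RTMidSpec",
    "BISSpec",
    "PopulationSpec",
    "SessionRecord",
    "sample_population",
    "simulate_session",
    "simulate_cohort",
    "sessions_to_table",
    "write_trial_table",
    "read_trial_table",
]

CONDITIONS = ("reward", "loss")


class SpecError(ValueError):
    """Infeasible or inconsistent population specification."""


@dataclass(frozen=True)
class RTDecisionSpec:
    """Linear structure of decision-phase reaction times (ms).

    rt = intercept + b_i + (condition_effect + b_c) * is_reward
         + (ratio_slope + b_r) * ratio + residual,
    with independent subject effects b_i, b_c, b_r; truncated to the 3 s
    response window.
    """

    intercept: float = 1043.17
    condition_effect: float = -34.82  # reward relative to loss
    ratio_slope: float = 241.67
    sd_intercept: float = 167.13
    sd_condition: float = 181.01
    sd_ratio: float = 279.04
    sd_residual: float = 299.79
    rt_min: float = 200.0
    rt_max: float = 1000.0 * DECISION_WINDOW_S


@dataclass(frozen=True)
class RTMidSpec:
    """Speeded (MID) reaction times: per-subject log-normal around ~240 ms."""

    mean: float = 239.72
    sd_subject: float = 18.91
    sd_residual: float = 46.86

    @property
    def log_sd(self) -> float:
        # coefficient of variation of the residual, mapped to log scale
        return self.sd_residual / self.mean


@dataclass(frozen=True)
class BISSpec:
    """BIS-15 subscale means/SDs (non-planning, motor, attentional)."""

    means: tuple = (9.50, 10.83, 8.73)
    sds: tuple = (2.81, 2.29, 1.64)
    lower: float = 5.0   # 5 items per subscale, 1..4 each
    upper: float = 20.0


@dataclass(frozen=True)
class PopulationSpec:
    """Population-level moments the cohort generator targets."""

    kappa_mean: dict = field(
        default_factory=lambda: {"reward": 0.33, "loss": 0.30}
    )
    kappa_sd: dict = field(default_factory=lambda: {"reward": 0.48, "loss": 0.32})
    kappa_cross_corr: float = 0.56
    beta_mean: dict = field(default_factory=lambda: {"reward": 0.38, "loss": 0.39})
    beta_sd: dict = field(default_factory=lambda: {"reward": 0.41, "loss": 0.39})
    miss_rate: float = 0.0156
    rt_decision: RTDecisionSpec = field(default_factory=RTDecisionSpec)
    rt_mid: RTMidSpec = field(default_factory=RTMidSpec)
    bis: BISSpec = field(default_factory=BISSpec)
    #: Optional point mass of non-discounters (kappa ~ 0); disabled by default
    #: so parameter-recovery checks see a continuous kappa distribution.
    nondiscounter_fraction: float = 0.0
    nondiscounter_kappa: float = 1e-4

    def __post_init__(self) -> None:
        for cond in CONDITIONS:
            if self.kappa_sd[cond] <= 0 or self.beta_sd[cond] <= 0:
                raise SpecError("standard deviations must be positive")
        if not -1.0 <= self.kappa_cross_corr <= 1.0:
            raise SpecError("|cross-correlation| must be <= 1")
        if not 0.0 <= self.miss_rate < 1.0:
            raise SpecError("miss_rate must lie in [0, 1)")
        if not 0.0 <= self.nondiscounter_fraction < 1.0:
            raise SpecError("nondiscounter_fraction must lie in [0, 1)")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given natural-scale mean and SD."""
    if mean <= 0:
        raise SpecError("log-normal mean must be positive")
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return mu, float(np.sqrt(sigma2))


def _log_scale_corr(spec: PopulationSpec) -> float:
    """Log-scale correlation reproducing the requested natural-scale correlation."""
    m1, s1 = spec.kappa_mean["reward"], spec.kappa_sd["reward"]
    m2, s2 = spec.kappa_mean["loss"], spec.kappa_sd["loss"]
    _, sig1 = _lognormal_params(m1, s1)
    _, sig2 = _lognormal_params(m2, s2)
    arg = 1.0 + spec.kappa_cross_corr * s1 * s2 / (m1 * m2)
    if arg <= 0:
        raise SpecError("requested kappa correlation is infeasible for these moments")
    rho_log = np.log(arg) / (sig1 * sig2)
    if abs(rho_log) > 1.0:
        raise SpecError("requested kappa correlation is infeasible for these moments")
    return float(rho_log)


def _truncnorm(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def sample_population(n: int, spec: PopulationSpec | None = None, seed: int = 0) -> pd.DataFrame:
    """Draw per-participant parameters for a synthetic cohort.

    (kappa_reward, kappa_loss) come from a moment-matched correlated bivariate
    log-normal; beta from truncated normals on [BETA_FLOOR, 1]; BIS-15
    subscales from truncated normals; MID speed and decision-RT random effects
    from normals.  Deterministic given ``seed``.
    """
    if n < 1:
        raise SpecError("n must be >= 1")
    spec = spec or PopulationSpec()
    rng = np.random.default_rng(seed)

    mu_r, sig_r = _lognormal_params(spec.kappa_mean["reward"], spec.kappa_sd["reward"])
    mu_l, sig_l = _lognormal_params(spec.kappa_mean["loss"], spec.kappa_sd["loss"])
    rho = _log_scale_corr(spec)
    cov = np.array(
        [[sig_r**2, rho * sig_r * sig_l], [rho * sig_r * sig_l, sig_l**2]]
    )
    z = rng.multivariate_normal([mu_r, mu_l], cov, size=n)
    kappa_reward = np.exp(z[:, 0])
    kappa_loss = np.exp(z[:, 1])

    if spec.nondiscounter_fraction > 0:
        mask = rng.random(n) < spec.nondiscounter_fraction
        kappa_reward[mask] = spec.nondiscounter_kappa
        kappa_loss[mask] = spec.nondiscounter_kappa

    beta_reward = _truncnorm(
        rng, spec.beta_mean["reward"], spec.beta_sd["reward"], BETA_FLOOR, 1.0, n
    )
    beta_loss = _truncnorm(
        rng, spec.beta_mean["loss"], spec.beta_sd["loss"], BETA_FLOOR, 1.0, n
    )

    bis = {
        name: _truncnorm(rng, m, s, spec.bis.lower, spec.bis.upper, n)
        for name, m, s in zip(
            ("bis_nonplanning", "bis_motor", "bis_attentional"),
            spec.bis.means,
            spec.bis.sds,
        )
    }

    rt = spec.rt_decision
    cohort = pd.DataFrame(
        {
            "participant": [f"sub-{i + 1:02d}" for i in range(n)],
            "kappa_reward": kappa_reward,
            "kappa_loss": kappa_loss,
            "beta_reward": beta_reward,
            "beta_loss": beta_loss,
            **bis,
            "rt_dec_intercept_offset": rng.normal(0.0, rt.sd_intercept, n),
            "rt_dec_condition_offset": rng.normal(0.0, rt.sd_condition, n),
            "rt_dec_ratio_offset": rng.normal(0.0, rt.sd_ratio, n),
            "rt_mid_mean": rng.normal(spec.rt_mid.mean, spec.rt_mid.sd_subject, n),
        }
    )
    cohort["bis_total"] = (
        cohort["bis_nonplanning"] + cohort["bis_motor"] + cohort["bis_attentional"]
    )
    return cohort


@dataclass
class SessionRecord:
    """One simulated participant-condition session.

    Holds the presented trials (in presentation order), the sampled choices
    and reaction times, the staircase trace, MID outcomes, realised payouts
    and the trial-phase timeline used to build fMRI event tables.
    """

    participant_id: str
    condition: str
    trials: list
    choices: list                  # "immediate" / "delayed" / None
    decision_rt_ms: list           # float or NaN for missed decisions
    staircase_thresholds: list     # window (ms) in effect on each trial
    mid_rt_ms: list
    mid_success: list
    payouts: list
    decision_onset_s: list
    anticipation_onset_s: list     # NaN for missed trials
    flash_onset_s: list
    feedback_onset_s: list
    seed: Optional[int] = None

    @property
    def n_trials(self) -> int:
        return len(self.trials)


def simulate_session(
    params: DiscountParams,
    grid: Sequence[TrialOption],
    spec: PopulationSpec | None = None,
    seed: int = 0,
    participant_id: str = "sub-01",
    order: Optional[np.ndarray] = None,
    rt_effects: Optional[dict] = None,
    staircase_start_ms: float = STAIRCASE_START_MS,
) -> SessionRecord:
    """Simulate one session of choices, reaction times, staircase and payouts.

    Choices are sampled from the softmax model at ``params``; decisions are
    missed at ``spec.miss_rate``; decision RTs follow the linear
    condition + ratio structure truncated to the 3 s window; the MID phase is
    played against log-normal speeded responses with the adaptive staircase;
    the timeline is assembled with uniform ISI (1-2 s) and ITI (1.5-5 s)
    jitters.
    """
    spec = spec or PopulationSpec()
    rng = np.random.default_rng(seed)
    grid = list(grid)
    if order is None:
        order = np.arange(len(grid))
    trials = [grid[i] for i in order]
    condition = trials[0].condition
    if any(t.condition != condition for t in trials):
        raise SpecError("mixed-condition grid")

    rt_effects = rt_effects or {
        "intercept_offset": 0.0,
        "condition_offset": 0.0,
        "ratio_offset": 0.0,
        "mid_mean": spec.rt_mid.mean,
    }

    p_disc = _discounted_probability(trials, params.kappa, params.beta)
    discounted_label = "immediate" if condition == "reward" else "delayed"
    other_label = "delayed" if condition == "reward" else "immediate"

    rts_spec = spec.rt_decision
    is_reward = 1.0 if condition == "reward" else 0.0
    scheme = PayoutScheme()
    state = StaircaseState(threshold=staircase_start_ms)
    mid_sigma = spec.rt_mid.log_sd

    choices, dec_rts, thresholds = [], [], []
    mid_rts, mid_ok, payouts = [], [], []
    dec_on, ant_on, fl_on, fb_on = [], [], [], []
    clock = 0.0

    for trial, p in zip(trials, p_disc):
        dec_on.append(clock)
        missed = rng.random() < spec.miss_rate
        if missed:
            choices.append(None)
            dec_rts.append(np.nan)
            thresholds.append(state.threshold)
            mid_rts.append(np.nan)
            mid_ok.append(False)
            payouts.append(0.0)
            ant_on.append(np.nan)
            fl_on.append(np.nan)
            fb_on.append(np.nan)
            clock += DECISION_WINDOW_S + rng.uniform(*ISI_RANGE_S)
            clock += rng.uniform(*ITI_RANGE_S)
            continue

        choice = discounted_label if rng.random() < p else other_label
        mu = (
            rts_spec.intercept
            + rt_effects["intercept_offset"]
            + (rts_spec.condition_effect + rt_effects["condition_offset"]) * is_reward
            + (rts_spec.ratio_slope + rt_effects["ratio_offset"]) * trial.ratio
        )
        rt = float(
            np.clip(rng.normal(mu, rts_spec.sd_residual), rts_spec.rt_min, rts_spec.rt_max)
        )
        choices.append(choice)
        dec_rts.append(rt)

        thresholds.append(state.threshold)
        mid_rt = float(rt_effects["mid_mean"] * np.exp(rng.normal(0.0, mid_sigma)))
        success = mid_rt <= state.threshold
        state = staircase_update(state, mid_rt)
        mid_rts.append(mid_rt)
        mid_ok.append(success)
        payouts.append(trial_payout(trial, choice, success, scheme))

        isi = rng.uniform(*ISI_RANGE_S)
        a = clock + DECISION_WINDOW_S + isi
        f = a + CUE_DURATION_S
        fb = f + FLASH_DURATION_S + 1.0  # 1 s response-collection window
        ant_on.append(a)
        fl_on.append(f)
        fb_on.append(fb)
        clock = fb + FEEDBACK_DURATION_S + rng.uniform(*ITI_RANGE_S)

    return SessionRecord(
        participant_id=participant_id,
        condition=condition,
        trials=trials,
        choices=choices,
        decision_rt_ms=dec_rts,
        staircase_thresholds=thresholds,
        mid_rt_ms=mid_rts,
        mid_success=mid_ok,
        payouts=payouts,
        decision_onset_s=dec_on,
        anticipation_onset_s=ant_on,
        flash_onset_s=fl_on,
        feedback_onset_s=fb_on,
        seed=seed,
    )


def simulate_cohort(
    n: int = 30,
    spec: PopulationSpec | None = None,
    seed: int = 0,
    trials_per_session: int = 32,
) -> tuple[pd.DataFrame, list[SessionRecord]]:
    """Full study replica: a cohort table plus reward and loss sessions each.

    The 32-trial grid is tiled when ``trials_per_session`` is a larger
    multiple of 32 (used for parameter-recovery calibration).  Session order
    is counterbalanced (even-indexed participants start with reward) and each
    participant reuses one presentation-order permutation across both
    sessions.
    """
    from .task_design import tile_grid  # local import to avoid cycle noise

    spec = spec or PopulationSpec()
    if trials_per_session % 32 != 0:
        raise SpecError("trials_per_session must be a multiple of 32")
    reps = trials_per_session // 32

    ss = np.random.SeedSequence(seed)
    pop_seed, *session_seeds = ss.spawn(1 + 2 * n)
    cohort = sample_population(n, spec, seed=int(pop_seed.generate_state(1)[0] % 2**31))

    grids = {
        cond: tile_grid(build_trial_grid(cond), reps) for cond in CONDITIONS
    }
    cohort["first_condition"] = [
        "reward" if i % 2 == 0 else "loss" for i in range(n)
    ]
    sessions: list[SessionRecord] = []
    for i, row in enumerate(cohort.itertuples(index=False)):
        order_seed = int(
            np.random.SeedSequence([seed, i]).generate_state(1)[0] % 2**31
        )
        order = shuffle_order(trials_per_session, order_seed)
        first = ("reward", "loss") if i % 2 == 0 else ("loss", "reward")
        rt_effects = {
            "intercept_offset": row.rt_dec_intercept_offset,
            "condition_offset": row.rt_dec_condition_offset,
            "ratio_offset": row.rt_dec_ratio_offset,
            "mid_mean": row.rt_mid_mean,
        }
        for j, cond in enumerate(first):
            sess_seed = int(
                session_seeds[2 * i + j].generate_state(1)[0] % 2**31
            )
            params = DiscountParams(
                kappa=getattr(row, f"kappa_{cond}"),
                beta=getattr(row, f"beta_{cond}"),
            )
            sessions.append(
                simulate_session(
                    params,
                    grids[cond],
                    spec,
                    seed=sess_seed,
                    participant_id=row.participant,
                    order=order,
                    rt_effects=rt_effects,
                )
            )
    return cohort, sessions


def sessions_to_table(sessions: Sequence[SessionRecord]) -> pd.DataFrame:
    """Long trial/choice table (one row per presented trial).

    This is the tabular interchange format the fitting and analysis stages
    read; missing choices are empty cells.
    """
    rows = []
    for s in sessions:
        for k, trial in enumerate(s.trials):
            rows.append(
                {
                    "participant": s.participant_id,
                    "condition": s.condition,
                    "trial_id": trial.trial_id,
                    "immediate_amount": trial.immediate_amount,
                    "delayed_amount": trial.delayed_amount,
                    "ratio": trial.ratio,
                    "delay_weeks": trial.delay,
                    "choice": s.choices[k],
                    "rt_ms": s.decision_rt_ms[k],
                }
            )
    return pd.DataFrame(rows)


def write_trial_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, na_rep="n/a", float_format="%.4f")


def read_trial_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["n/a"])
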