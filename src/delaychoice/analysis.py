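"""Behavioural statistics: discounted-choice counting, aggregation, exclusions,
correlations with Fisher-z intervals, paired tests and power analyses.

The "discounted" choice is the immediate option in the reward condition and
the delayed option in the loss condition.  Mixed-effects models on the
aggregated tables are deliberately left to standard tooling (lme4 and
friends); this module produces their exact input tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import integrate, special, stats

__all__ = [
    "AnalysisError",
    "CorrelationResult",
    "count_discounted",
    "discounted_counts_table",
    "frequency_by_ratio",
    "exclude_no_variability",
    "pearson_with_ci",
    "paired_t",
    "power_correlation",
    "power_paired_t",
    "excluded_trial_percentage",
    "build_cohort_table",
    "table1_summary",
]


class AnalysisError(ValueError):
    """Degenerate or invalid analysis input."""


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with Fisher-z 95 % interval and two-sided p."""

    r: float
    ci_low: float
    ci_high: float
    p: float
    n: int


def _is_discounted(condition: str, choice: str) -> bool:
    return (condition == "reward" and choice == "immediate") or (
        condition == "loss" and choice == "delayed"
    )


def count_discounted(session) -> int:
    """Number of discounted choices in one session (missing trials excluded)."""
    valid = [c for c in session.choices if c in ("immediate", "delayed")]
    if not valid:
        raise AnalysisError("session has no recorded choices")
    return sum(_is_discounted(session.condition, c) for c in valid)


def _clean(trial_table: pd.DataFrame) -> pd.DataFrame:
    df = trial_table.copy()
    df = df[df["choice"].isin(["immediate", "delayed"])]
    return df


def discounted_counts_table(trial_table: pd.DataFrame) -> pd.DataFrame:
    """Per participant x condition: discounted-choice count and valid-trial count."""
    df = _clean(trial_table)
    df["discounted"] = [
        _is_discounted(c, ch) for c, ch in zip(df["condition"], df["choice"])
    ]
    out = (
        df.groupby(["participant", "condition"])
        .agg(n_discounted=("discounted", "sum"), n_valid=("discounted", "size"))
        .reset_index()
    )
    return out


def frequency_by_ratio(trial_table: pd.DataFrame) -> pd.DataFrame:
    """Relative frequency of discounted choices per participant, condition, ratio.

    The long-format table a mixed model of the form
    ``relative_frequency ~ condition + ratio + (condition + ratio | subject)``
    consumes.  Missing trials are dropped from both numerator and denominator.
    """
    df = _clean(trial_table)
    df["discounted"] = [
        _is_discounted(c, ch) for c, ch in zip(df["condition"], df["choice"])
    ]
    out = (
        df.groupby(["participant", "condition", "ratio"])
        .agg(
            n_discounted=("discounted", "sum"),
            n_trials=("discounted", "size"),
        )
        .reset_index()
    )
    out["relative_frequency"] = out["n_discounted"] / out["n_trials"]
    return out


def exclude_no_variability(counts: pd.DataFrame, warn: bool = True) -> pd.DataFrame:
    """Drop participants with constant choices in at least one condition.

    ``counts`` is the output of :func:`discounted_counts_table`.  A
    participant-condition cell is non-variable when the discounted count is 0
    or equals the number of valid trials (a boundary, typically
    non-identified, likelihood).
    """
    constant = (counts["n_discounted"] == 0) | (
        counts["n_discounted"] == counts["n_valid"]
    )
    dropped = set(counts.loc[constant, "participant"])
    kept = counts[~counts["participant"].isin(dropped)].reset_index(drop=True)
    if kept.empty and warn:
        import warnings

        warnings.warn("no participants retained after variability exclusion")
    return kept


def pearson_with_ci(x, y, conf: float = 0.95) -> CorrelationResult:
    """Pearson r with Fisher-z confidence interval and two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise AnalysisError("x and y must be equal-length 1-d arrays")
    n = x.size
    if n < 4:
        raise AnalysisError("need at least 4 pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise AnalysisError("non-finite values")
    if np.std(x) == 0 or np.std(y) == 0:
        raise AnalysisError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    z = np.arctanh(r)
    se = 1.0 / math.sqrt(n - 3)
    zcrit = stats.norm.ppf(0.5 + conf / 2.0)
    return CorrelationResult(
        r=float(r),
        ci_low=float(np.tanh(z - zcrit * se)),
        ci_high=float(np.tanh(z + zcrit * se)),
        p=float(p),
        n=int(n),
    )


def paired_t(x, y) -> tuple[float, int, float]:
    """Paired t-test; returns (t, df, two-sided p) with df = n - 1."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise AnalysisError("need equal-length 1-d arrays with n >= 2")
    d = x - y
    if np.std(d, ddof=1) == 0:
        if np.all(d == 0):
            # identical samples: t = 0 with p = 1 by convention
            return 0.0, int(x.size - 1), 1.0
        raise AnalysisError("zero-variance nonzero differences: test degenerate")
    t, p = stats.ttest_rel(x, y)
    return float(t), int(x.size - 1), float(p)


# ---------------------------------------------------------------------------
# power analyses


def _check_power_args(n: int, alpha: float, tails: int) -> None:
    if not 0 < alpha < 1:
        raise AnalysisError("alpha must lie in (0, 1)")
    if tails not in (1, 2):
        raise AnalysisError("tails must be 1 or 2")
    if n <= 3:
        raise AnalysisError("n must exceed 3")


def _r_density(r: float, rho: float, n: int) -> float:
    """Exact density of the sample Pearson r under bivariate normality."""
    lg = (
        np.log(n - 2)
        + special.gammaln(n - 1)
        + (n - 1) / 2.0 * np.log1p(-rho**2)
        + (n - 4) / 2.0 * np.log1p(-r**2)
        - 0.5 * np.log(2 * np.pi)
        - special.gammaln(n - 0.5)
        - (n - 1.5) * np.log1p(-rho * r)
    )
    return float(np.exp(lg) * special.hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1) / 2.0))


def _r_critical(n: int, alpha: float, tails: int) -> float:
    tcrit = stats.t.ppf(1.0 - alpha / tails, n - 2)
    return float(tcrit / math.sqrt(n - 2 + tcrit**2))


def power_correlation(
    rho: float,
    n: int,
    alpha: float = 0.05,
    tails: int = 1,
    method: str = "exact",
    n_sim: int = 100_000,
    seed: int = 0,
) -> float:
    """Power to reject rho = 0 when the true correlation is ``rho``.

    Methods
    -------
    exact : integrate the exact sampling distribution of r over the rejection
        region (reference method).
    nct : noncentral-t approximation with noncentrality rho*sqrt(n)/sqrt(1-rho^2),
        df = n - 2 (the convention of common power software).
    fisher : Fisher-z normal approximation.
    montecarlo : seeded simulation with ``n_sim`` bivariate-normal replicates.
    """
    if not 0 < rho < 1:
        raise AnalysisError("rho must lie in (0, 1)")
    _check_power_args(n, alpha, tails)
    rcrit = _r_critical(n, alpha, tails)
    if method == "exact":
        hi, _ = integrate.quad(_r_density, rcrit, 1.0, args=(rho, n))
        if tails == 2:
            lo, _ = integrate.quad(_r_density, -1.0, -rcrit, args=(rho, n))
            hi += lo
        return float(hi)
    if method == "nct":
        df = n - 2
        nc = rho / math.sqrt(1 - rho**2) * math.sqrt(n)
        tcrit = stats.t.ppf(1 - alpha / tails, df)
        power = 1.0 - stats.nct.cdf(tcrit, df, nc)
        if tails == 2:
            power += stats.nct.cdf(-tcrit, df, nc)
        return float(power)
    if method == "fisher":
        zrho = np.arctanh(rho)
        se = 1.0 / math.sqrt(n - 3)
        zcrit = stats.norm.ppf(1 - alpha / tails)
        power = 1.0 - stats.norm.cdf(zcrit - zrho / se)
        if tails == 2:
            power += stats.norm.cdf(-zcrit - zrho / se)
        return float(power)
    if method == "montecarlo":
        if n_sim < 10_000:
            raise AnalysisError("montecarlo method needs >= 10^4 replicates")
        rng = np.random.default_rng(seed)
        cov = np.array([[1.0, rho], [rho, 1.0]])
        xy = rng.multivariate_normal([0.0, 0.0], cov, size=(n_sim, n))
        xc = xy - xy.mean(axis=1, keepdims=True)
        num = (xc[:, :, 0] * xc[:, :, 1]).sum(axis=1)
        den = np.sqrt((xc[:, :, 0] ** 2).sum(1) * (xc[:, :, 1] ** 2).sum(1))
        r = num / den
        reject = r > rcrit
        if tails == 2:
            reject |= r < -rcrit
        return float(reject.mean())
    raise AnalysisError(f"unknown method {method!r}")


def power_paired_t(d: float, n: int, alpha: float = 0.05, tails: int = 1) -> float:
    """Noncentral-t power of a paired t-test for effect size d (Cohen's d_z)."""
    if d <= 0:
        raise AnalysisError("d must be positive")
    if n < 2:
        raise AnalysisError("n must be >= 2")
    if not 0 < alpha < 1:
        raise AnalysisError("alpha must lie in (0, 1)")
    if tails not in (1, 2):
        raise AnalysisError("tails must be 1 or 2")
    df = n - 1
    nc = d * math.sqrt(n)
    tcrit = stats.t.ppf(1 - alpha / tails, df)
    power = 1.0 - stats.nct.cdf(tcrit, df, nc)
    if tails == 2:
        power += stats.nct.cdf(-tcrit, df, nc)
    return float(power)


def excluded_trial_percentage(
    n_excluded: int, n_participants: int, trials_per_participant: int
) -> float:
    """Percentage of all trials excluded (e.g. missed decisions)."""
    if min(n_excluded, n_participants, trials_per_participant) < 0:
        raise AnalysisError("counts must be non-negative")
    total = n_participants * trials_per_participant
    if total == 0:
        raise AnalysisError("zero total trials")
    return 100.0 * n_excluded / total


# ---------------------------------------------------------------------------
# cohort summary


def build_cohort_table(
    params_table: pd.DataFrame,
    trial_table: pd.DataFrame,
    bis_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Wide per-participant summary: parameters, counts, BIS scores.

    ``params_table`` is the fit_cohort output; ``bis_table`` (optional) has
    one row per participant with bis_* columns.
    """
    counts = discounted_counts_table(trial_table)
    wide = params_table.pivot(
        index="participant", columns="condition", values=["kappa", "beta", "boundary_flag"]
    )
    wide.columns = [f"{a}_{b}" for a, b in wide.columns]
    cw = counts.pivot(index="participant", columns="condition", values="n_discounted")
    cw.columns = [f"n_discounted_{c}" for c in cw.columns]
    out = wide.join(cw).reset_index()
    if bis_table is not None:
        out = out.merge(bis_table, on="participant", how="left")
    return out


_TABLE1_VARS = [
    ("kappa_reward", "kappa (reward)"),
    ("kappa_loss", "kappa (loss)"),
    ("beta_reward", "beta (reward)"),
    ("beta_loss", "beta (loss)"),
    ("n_discounted_reward", "discounted choices (reward)"),
    ("n_discounted_loss", "discounted choices (loss)"),
    ("bis_nonplanning", "BIS non-planning"),
    ("bis_motor", "BIS motor"),
    ("bis_attentional", "BIS attentional"),
    ("bis_total", "BIS total"),
]


def table1_summary(cohort_table: pd.DataFrame) -> dict:
    """Means, SDs and pairwise correlations (with CIs) of the key variables.

    Returns {"descriptives": DataFrame, "correlations": DataFrame} in the
    style of a study's descriptive table.
    """
    present = [(c, label) for c, label in _TABLE1_VARS if c in cohort_table.columns]
    desc_rows = []
    for col, label in present:
        v = cohort_table[col].astype(float)
        desc_rows.append({"variable": label, "mean": v.mean(), "sd": v.std(ddof=1)})
    corr_rows = []
    for i in range(len(present)):
        for j in range(i):
            xi, li = present[i]
            xj, lj = present[j]
            try:
                res = pearson_with_ci(cohort_table[xi], cohort_table[xj])
            except AnalysisError:
                continue
            corr_rows.append(
                {
                    "var_a": li,
                    "var_b": lj,
                    "r": res.r,
                    "ci_low": res.ci_low,
                    "ci_high": res.ci_high,
                    "p": res.p,
                    "n": res.n,
                }
            )
    return {
        "descriptives": pd.DataFrame(desc_rows),
        "correlations": pd.DataFrame(corr_rows),
    }
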