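"""Behavioural statistics: counting, aggregation, exclusions, tests, power."""

import numpy as np
import pandas as pd
import pytest

from delaychoice.analysis import (
    AnalysisError,
    build_cohort_table,
    count_discounted,
    discounted_counts_table,
    exclude_no_variability,
    excluded_trial_percentage,
    frequency_by_ratio,
    paired_t,
    pearson_with_ci,
    power_correlation,
    power_paired_t,
    table1_summary,
)
from delaychoice.model import BETA_FLOOR, DiscountParams, fit_cohort
from delaychoice.simulate import (
    PopulationSpec,
    sessions_to_table,
    simulate_cohort,
    simulate_session,
)
from delaychoice.task_design import build_trial_grid


def _session(condition, choices):
    """Minimal stand-in session object for counting."""

    class S:
        pass

    s = S()
    s.condition = condition
    s.choices = choices
    return s


class TestCountDiscounted:
    def test_reward_all_delayed_counts_zero(self):
        assert count_discounted(_session("reward", ["delayed"] * 32)) == 0

    def test_loss_all_delayed_counts_all(self):
        assert count_discounted(_session("loss", ["delayed"] * 32)) == 32

    def test_constructed_count(self):
        choices = ["immediate"] * 5 + ["delayed"] * 26 + [None]
        assert count_discounted(_session("reward", choices)) == 5

    def test_all_missing_raises(self):
        with pytest.raises(AnalysisError):
            count_discounted(_session("reward", [None] * 32))


class TestFrequencyByRatio:
    def test_all_discounting_participant(self, simple_trial_table):
        freq = frequency_by_ratio(simple_trial_table)
        sub1 = freq[freq["participant"] == "sub-01"]  # always immediate, reward
        assert (sub1["relative_frequency"] == 1.0).all()
        sub2 = freq[freq["participant"] == "sub-02"]
        assert (sub2["relative_frequency"] == 0.0).all()

    def test_deterministic_threshold_participant(self):
        """kappa between the 0.4 and 0.6 indifference points discounts
        exactly at ratios 0.6 and 0.8 when choice noise is at the floor."""
        grid = build_trial_grid("reward")
        s = simulate_session(
            DiscountParams(0.5, BETA_FLOOR),
            grid,
            PopulationSpec(miss_rate=0.0),
            seed=0,
            participant_id="sub-01",
        )
        freq = frequency_by_ratio(sessions_to_table([s]))
        by_ratio = freq.set_index("ratio")["relative_frequency"]
        assert by_ratio.loc[0.2] == 0.0 and by_ratio.loc[0.4] == 0.0
        assert by_ratio.loc[0.6] == 1.0 and by_ratio.loc[0.8] == 1.0

    def test_partial_cell(self, trial_table_row):
        rows = [
            trial_table_row("sub-01", "reward", 0.4, c, i)
            for i, c in enumerate(
                ["immediate", "immediate"] + ["delayed"] * 6
            )
        ]
        freq = frequency_by_ratio(pd.DataFrame(rows))
        assert freq["relative_frequency"].iloc[0] == pytest.approx(0.25)

    def test_missing_dropped_from_both_counts(self, trial_table_row):
        rows = [
            trial_table_row("sub-01", "reward", 0.4, c, i)
            for i, c in enumerate(["immediate", None, "delayed", None])
        ]
        freq = frequency_by_ratio(pd.DataFrame(rows))
        assert freq["n_trials"].iloc[0] == 2
        assert freq["relative_frequency"].iloc[0] == pytest.approx(0.5)

    def test_pure_function(self, simple_trial_table):
        a = frequency_by_ratio(simple_trial_table)
        b = frequency_by_ratio(simple_trial_table)
        pd.testing.assert_frame_equal(a, b)


class TestExcludeNoVariability:
    def _counts(self, entries):
        return pd.DataFrame(
            [
                {
                    "participant": p,
                    "condition": c,
                    "n_discounted": k,
                    "n_valid": n,
                }
                for p, c, k, n in entries
            ]
        )

    def test_zero_count_participant_dropped(self):
        counts = self._counts(
            [
                ("sub-01", "reward", 5, 32),
                ("sub-01", "loss", 0, 32),
                ("sub-02", "reward", 4, 32),
                ("sub-02", "loss", 7, 31),
            ]
        )
        kept = exclude_no_variability(counts)
        assert set(kept["participant"]) == {"sub-02"}

    def test_saturated_participant_dropped(self):
        counts = self._counts([("sub-01", "reward", 32, 32), ("sub-01", "loss", 3, 32)])
        kept = exclude_no_variability(counts, warn=False)
        assert kept.empty

    def test_variable_participant_kept(self):
        counts = self._counts([("sub-01", "reward", 1, 32), ("sub-01", "loss", 31, 32)])
        kept = exclude_no_variability(counts)
        assert set(kept["participant"]) == {"sub-01"}

    def test_empty_result_warns(self):
        counts = self._counts([("sub-01", "reward", 0, 32)])
        with pytest.warns(UserWarning):
            exclude_no_variability(counts)


class TestPearsonWithCI:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        res = pearson_with_ci(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p < 1e-9

    def test_printed_interval_for_r56_n30(self):
        # construct a sample whose Pearson r is exactly 0.56
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        e = rng.normal(size=30)
        x = (x - x.mean()) / x.std()
        e = e - e.mean()
        e = e - x * np.dot(x, e) / np.dot(x, x)  # orthogonalize
        e = e / e.std()
        rho = 0.56
        y = rho * x + np.sqrt(1 - rho**2) * e
        res = pearson_with_ci(x, y)
        assert res.r == pytest.approx(0.56, abs=1e-12)
        assert round(res.ci_low, 2) == 0.25
        assert round(res.ci_high, 2) == 0.77

    def test_shuffled_pairing_near_zero(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=5000)
        y = rng.permutation(x)
        assert abs(pearson_with_ci(x, y).r) < 0.05

    def test_agrees_with_permutation_p(self):
        rng = np.random.default_rng(2)
        n = 20
        x = rng.normal(size=n)
        y = 0.45 * x + rng.normal(size=n)
        res = pearson_with_ci(x, y)
        perm = np.empty(10_000)
        for i in range(10_000):
            perm[i] = np.corrcoef(x, rng.permutation(y))[0, 1]
        p_perm = (np.abs(perm) >= abs(res.r)).mean()
        assert p_perm == pytest.approx(res.p, abs=0.02)

    def test_degenerate_inputs(self):
        with pytest.raises(AnalysisError):
            pearson_with_ci([1, 1, 1, 1], [1, 2, 3, 4])
        with pytest.raises(AnalysisError):
            pearson_with_ci([1, 2, 3], [1, 2, 3])


class TestPairedT:
    def test_identical_samples(self):
        t, df, p = paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0 and df == 2

    def test_df_for_n30(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=30), rng.normal(size=30)
        _, df, _ = paired_t(x, y)
        assert df == 29

    def test_antisymmetry(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=12), rng.normal(size=12)
        t_xy, _, p_xy = paired_t(x, y)
        t_yx, _, p_yx = paired_t(y, x)
        assert t_xy == pytest.approx(-t_yx)
        assert p_xy == pytest.approx(p_yx)

    def test_constant_nonzero_difference_degenerate(self):
        with pytest.raises(AnalysisError):
            paired_t([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])


class TestPowerCorrelation:
    def test_exact_reference_values(self):
        # frozen from integrating the exact r-density; Monte Carlo verified
        assert power_correlation(0.55, 30, 0.05, tails=1) == pytest.approx(
            0.9483, abs=1e-3
        )
        assert power_correlation(0.39, 30, 0.05, tails=1) == pytest.approx(
            0.7049, abs=1e-3
        )

    def test_nct_convention_matches_power_software(self):
        assert power_correlation(0.55, 30, 0.05, 1, method="nct") == pytest.approx(
            0.9695, abs=1e-3
        )
        assert power_correlation(0.39, 30, 0.05, 1, method="nct") == pytest.approx(
            0.7318, abs=1e-3
        )

    def test_size_at_zero_effect(self):
        assert power_correlation(1e-9, 30, 0.05, tails=1) == pytest.approx(
            0.05, abs=1e-3
        )

    def test_monotone_in_effect_and_n(self):
        powers_rho = [power_correlation(r, 30) for r in (0.1, 0.3, 0.5, 0.7)]
        assert all(np.diff(powers_rho) > 0)
        powers_n = [power_correlation(0.4, n) for n in (10, 20, 40, 80)]
        assert all(np.diff(powers_n) > 0)

    def test_methods_agree_roughly(self):
        exact = power_correlation(0.45, 25, tails=2)
        fisher = power_correlation(0.45, 25, tails=2, method="fisher")
        mc = power_correlation(0.45, 25, tails=2, method="montecarlo", seed=5)
        assert fisher == pytest.approx(exact, abs=0.03)
        assert mc == pytest.approx(exact, abs=0.01)

    def test_domain_errors(self):
        with pytest.raises(AnalysisError):
            power_correlation(0.5, 3)
        with pytest.raises(AnalysisError):
            power_correlation(0.5, 30, alpha=0.0)
        with pytest.raises(AnalysisError):
            power_correlation(0.5, 30, tails=3)
        with pytest.raises(AnalysisError):
            power_correlation(1.2, 30)


class TestPowerPairedT:
    def test_small_effect_reference_value(self):
        assert power_paired_t(0.3, 30, 0.05, tails=1) == pytest.approx(0.484, abs=1e-3)

    def test_size_at_zero_effect(self):
        assert power_paired_t(1e-9, 30, 0.05, tails=1) == pytest.approx(0.05, abs=1e-3)

    def test_monotone_in_n(self):
        powers = [power_paired_t(0.3, n) for n in range(10, 101, 10)]
        assert all(np.diff(powers) > 0)

    def test_domain_errors(self):
        with pytest.raises(AnalysisError):
            power_paired_t(-0.1, 30)
        with pytest.raises(AnalysisError):
            power_paired_t(0.3, 1)


class TestExcludedTrialPercentage:
    @pytest.mark.parametrize(
        "args, expected",
        [((30, 30, 64), 1.5625), ((0, 30, 64), 0.0), ((64, 1, 64), 100.0)],
    )
    def test_values(self, args, expected):
        assert excluded_trial_percentage(*args) == pytest.approx(expected)

    def test_zero_denominator(self):
        with pytest.raises(AnalysisError):
            excluded_trial_percentage(1, 0, 64)


@pytest.fixture(scope="module")
def cohort_pieces():
    cohort, sessions = simulate_cohort(n=8, seed=12)
    table = sessions_to_table(sessions)
    fits = fit_cohort(table, n_starts=4, seed=12)
    return cohort, table, fits


class TestCohortSummary:
    def test_build_cohort_table_shape(self, cohort_pieces):
        cohort, table, fits = cohort_pieces
        bis = cohort[
            ["participant", "bis_nonplanning", "bis_motor", "bis_attentional", "bis_total"]
        ]
        wide = build_cohort_table(fits, table, bis)
        assert len(wide) == 8
        for col in ("kappa_reward", "kappa_loss", "n_discounted_reward", "bis_total"):
            assert col in wide.columns
        assert wide["bis_total"].equals(
            wide["bis_nonplanning"] + wide["bis_motor"] + wide["bis_attentional"]
        )

    def test_table1_summary_structure(self, cohort_pieces):
        cohort, table, fits = cohort_pieces
        wide = build_cohort_table(fits, table)
        out = table1_summary(wide)
        assert {"variable", "mean", "sd"} <= set(out["descriptives"].columns)
        corr = out["correlations"]
        assert ((corr["ci_low"] <= corr["r"]) & (corr["r"] <= corr["ci_high"])).all()

    def test_group_frequency_monotone_in_ratio(self):
        """Cohort-average discounting frequency rises with the amount ratio."""
        _, sessions = simulate_cohort(n=30, seed=21)
        freq = frequency_by_ratio(sessions_to_table(sessions))
        for cond in ("reward", "loss"):
            sub = freq[freq["condition"] == cond]
            means = sub.groupby("ratio")["relative_frequency"].mean()
            assert means.is_monotonic_increasing
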