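"""Tests for outcome summaries and repeated-measures statistics.

The ANOVA and Tukey routines are checked against independent oracles: a
brute-force within-subject sums-of-squares decomposition written here from
first principles, the paired-t/F equivalence for two-level factors, and the
studentized-range identity q = t * sqrt(2).
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from reflexsim import HReflexParams
from reflexsim.environment import Condition, RunLog, TrialRecord
from reflexsim.stats import rm_anova, summaries_to_frame, summarize_run, tukey_hsd

from conftest import make_run_state


def make_log(thetas, hsims, condition=None, successes=None):
    condition = condition or Condition("C5", "Kr", "LV", "MT")
    trials = []
    for i, (th, h) in enumerate(zip(thetas, hsims)):
        delta = None if i == 0 else (th - thetas[i - 1] + 180) % 360 - 180
        s = None if successes is None else successes[i]
        trials.append(
            TrialRecord(k=i + 1, theta_k=th, theta_tar=0.0, beta_k=1.0,
                        hsim_k=h, success=s, delta_theta_k=delta)
        )
    succ = [s for s in (successes or []) if s is not None]
    return RunLog(condition=condition, trials=trials, seed=0, score=0,
                  success_rate=(sum(succ) / len(succ)) if succ else None)


# ---------------------------------------------------------------- summaries

class TestSummarizeRun:
    def test_constant_dial_gives_zero_strategy(self):
        s = summarize_run(make_log([90, 90, 90], [0.5, 0.6, 0.7]))
        assert s.strategy == 0.0
        assert s.performance == pytest.approx(0.6)

    def test_strategy_is_mean_absolute_step(self):
        s = summarize_run(make_log([0, 10, 20], [0.5, 0.5, 0.5]))
        assert s.strategy == pytest.approx(10.0)

    def test_strategy_wraps_across_zero(self):
        s = summarize_run(make_log([350, 10], [0.5, 0.5]))
        assert s.strategy == pytest.approx(20.0)

    def test_noiseless_run_on_target_scores_best_performance(self):
        state = make_run_state(theta_tar=77.0, theta0=77.0)
        for _ in range(35):
            state.commit()
        s = summarize_run(state.to_log())
        assert s.performance == pytest.approx(0.5)
        assert s.strategy == 0.0
        assert s.success_rate == 1.0

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            summarize_run(make_log([0], [0.5]))

    def test_rotation_invariance_of_both_outcomes(self):
        thetas = [10, 40, 350, 200, 230]
        hsims = [0.6, 0.7, 0.9, 0.55, 0.8]
        base = summarize_run(make_log(thetas, hsims))
        rot = summarize_run(make_log([(t + 123.4) % 360 for t in thetas], hsims))
        assert rot.performance == pytest.approx(base.performance)
        assert rot.strategy == pytest.approx(base.strategy)


# ------------------------------------------------------- brute-force oracle

def oracle_oneway_rm(wide: np.ndarray):
    """One-way within-subject F from the raw sums-of-squares definition."""
    n, k = wide.shape
    grand = wide.mean()
    ss_treat = n * ((wide.mean(axis=0) - grand) ** 2).sum()
    resid = wide - wide.mean(axis=1, keepdims=True) - wide.mean(axis=0, keepdims=True) + grand
    ss_err = (resid**2).sum()
    f = (ss_treat / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))
    p = sps.f.sf(f, k - 1, (n - 1) * (k - 1))
    return f, p


def oracle_twoway_rm(cube: np.ndarray):
    """Two-way within-subject F statistics from cell means.

    ``cube`` is subjects x levels(A) x levels(B); each effect is tested
    against its own subject-interaction error term.
    """
    n, a, b = cube.shape
    grand = cube.mean()
    m_s = cube.mean(axis=(1, 2))
    m_a = cube.mean(axis=(0, 2))
    m_b = cube.mean(axis=(0, 1))
    m_sa = cube.mean(axis=2)
    m_sb = cube.mean(axis=1)
    m_ab = cube.mean(axis=0)

    ss_a = n * b * ((m_a - grand) ** 2).sum()
    ss_b = n * a * ((m_b - grand) ** 2).sum()
    ss_ab = n * ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_sa = b * ((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2).sum()
    ss_sb = a * ((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_sab = (
        (cube - m_sa[:, :, None] - m_sb[:, None, :] - m_ab[None, :, :]
         + m_s[:, None, None] + m_a[None, :, None] + m_b[None, None, :] - grand) ** 2
    ).sum()

    f_a = (ss_a / (a - 1)) / (ss_sa / ((n - 1) * (a - 1)))
    f_b = (ss_b / (b - 1)) / (ss_sb / ((n - 1) * (b - 1)))
    f_ab = (ss_ab / ((a - 1) * (b - 1))) / (ss_sab / ((n - 1) * (a - 1) * (b - 1)))
    return f_a, f_b, f_ab


def _long(wide, factor="cond"):
    n, k = wide.shape
    rows = [
        {"participant": f"P{i}", factor: f"L{j}", "performance": wide[i, j]}
        for i in range(n)
        for j in range(k)
    ]
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_identical_condition_means_give_null_f(self):
        base = np.array([[0.5], [0.7], [0.6], [0.65]])
        wide = np.repeat(base, 3, axis=1)  # no condition effect at all
        out = rm_anova(_long(wide), dv="performance", within="cond")
        assert out.loc[0, "F"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc[0, "p_unc"] == pytest.approx(1.0)

    def test_two_level_factor_equals_squared_paired_t(self):
        rng = np.random.default_rng(5)
        wide = rng.normal(0.7, 0.1, size=(8, 2))
        out = rm_anova(_long(wide), dv="performance", within="cond")
        t, p = sps.ttest_rel(wide[:, 0], wide[:, 1])
        assert out.loc[0, "F"] == pytest.approx(t**2, rel=1e-10)
        assert out.loc[0, "p_unc"] == pytest.approx(p, rel=1e-10)

    def test_oneway_matches_brute_force_sums_of_squares(self):
        rng = np.random.default_rng(9)
        wide = rng.normal(0.7, 0.1, size=(6, 4))
        out = rm_anova(_long(wide), dv="performance", within="cond")
        f, p = oracle_oneway_rm(wide)
        assert out.loc[0, "F"] == pytest.approx(f, rel=1e-10)
        assert out.loc[0, "p_unc"] == pytest.approx(p, rel=1e-10)
        assert out.loc[0, "df1"] == 3 and out.loc[0, "df2"] == 15

    def test_twoway_matches_brute_force_sums_of_squares(self):
        rng = np.random.default_rng(11)
        cube = rng.normal(0.7, 0.1, size=(4, 3, 2))
        rows = [
            {"participant": f"P{i}", "a": f"A{j}", "b": f"B{m}", "performance": cube[i, j, m]}
            for i, j, m in itertools.product(range(4), range(3), range(2))
        ]
        out = rm_anova(pd.DataFrame(rows), dv="performance", within=["a", "b"])
        f_a, f_b, f_ab = oracle_twoway_rm(cube)
        got = dict(zip(out["effect"], out["F"]))
        assert got["a"] == pytest.approx(f_a, rel=1e-10)
        assert got["b"] == pytest.approx(f_b, rel=1e-10)
        assert got["a * b"] == pytest.approx(f_ab, rel=1e-10)
        assert out["p_gg"].notna().all()  # GG-corrected p reported alongside

    def test_unbalanced_design_names_missing_cells(self):
        df = _long(np.zeros((3, 3)))
        df = df[~((df["participant"] == "P1") & (df["cond"] == "L2"))]
        with pytest.raises(ValueError, match="P1"):
            rm_anova(df, dv="performance", within="cond")

    def test_replicate_runs_are_averaged_per_cell(self):
        wide = np.array([[0.5, 0.9], [0.6, 0.8], [0.4, 0.7]])
        df = _long(wide)
        doubled = pd.concat([df, df], ignore_index=True)  # two identical runs/cell
        a = rm_anova(df, dv="performance", within="cond")
        b = rm_anova(doubled, dv="performance", within="cond")
        assert a.loc[0, "F"] == pytest.approx(b.loc[0, "F"], rel=1e-12)


class TestTukeyHSD:
    def test_identical_level_means_not_significant(self):
        wide = np.repeat(np.random.default_rng(0).normal(size=(5, 1)), 3, axis=1)
        out = tukey_hsd(_long(wide), dv="performance", within="cond")
        assert not out["significant"].any()
        assert (out["diff"] == 0).all()

    def test_two_levels_reduce_to_paired_comparison(self):
        rng = np.random.default_rng(3)
        wide = rng.normal(0.7, 0.05, size=(9, 2))
        out = tukey_hsd(_long(wide), dv="performance", within="cond")
        t, p = sps.ttest_rel(wide[:, 0], wide[:, 1])
        assert out.loc[0, "q"] == pytest.approx(abs(t) * np.sqrt(2), rel=1e-10)
        assert out.loc[0, "p_tukey"] == pytest.approx(p, rel=1e-6)

    def test_three_level_critical_value_matches_tabulation(self):
        # studentized range upper 5% point for k = 3, df = 12 is 3.773
        assert sps.studentized_range.ppf(0.95, 3, 12) == pytest.approx(3.773, abs=2e-3)
        rng = np.random.default_rng(8)
        wide = rng.normal(0.7, 0.05, size=(7, 3))
        out = tukey_hsd(_long(wide), dv="performance", within="cond")
        n, df_err = 7, 12
        ms_err = (out.loc[0, "se"] ** 2) * n / 2
        for _, row in out.iterrows():
            q_crit = sps.studentized_range.ppf(0.95, 3, df_err)
            assert row["significant"] == (abs(row["diff"]) / np.sqrt(ms_err / n) > q_crit)

    def test_antisymmetric_under_level_swap(self):
        rng = np.random.default_rng(4)
        wide = rng.normal(size=(6, 2))
        out = tukey_hsd(_long(wide), dv="performance", within="cond")
        flipped = tukey_hsd(_long(wide[:, ::-1]), dv="performance", within="cond")
        assert out.loc[0, "diff"] == pytest.approx(-flipped.loc[0, "diff"])
        assert out.loc[0, "p_tukey"] == pytest.approx(flipped.loc[0, "p_tukey"])

    def test_single_level_rejected(self):
        with pytest.raises(ValueError):
            tukey_hsd(_long(np.zeros((4, 1))), dv="performance", within="cond")


class TestSummariesFrame:
    def test_long_form_columns(self):
        logs = [make_log([0, 10, 20], [0.5, 0.6, 0.7])]
        df = summaries_to_frame([summarize_run(l) for l in logs])
        assert list(df.columns) == [
            "participant", "session", "run", "condition_id", "feedback_type",
            "variability", "threshold", "performance", "strategy", "success_rate",
        ]
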