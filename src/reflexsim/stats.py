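"""Outcome measures and repeated-measures comparisons.

Two outcomes summarize a run: *performance*, the mean peak-to-peak magnitude
of the simulated reflex over the run's trials (lower is better for
down-conditioning), and *operant strategy*, the mean absolute trial-to-trial
change in dial angle (degrees, wrapped to [0, 180]) — a proxy for how
aggressively the player explores.

Condition effects are assessed with one- or two-way repeated-measures ANOVA
(uncorrected and Greenhouse-Geisser-corrected p-values side by side) and
Tukey HSD pairwise comparisons using the within-subject error term.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps

from .environment import Condition, RunLog

__all__ = ["ConditionSummary", "summarize_run", "summaries_to_frame", "rm_anova", "tukey_hsd"]


@dataclass(frozen=True)
class ConditionSummary:
    condition: Condition
    performance: float
    strategy: float
    success_rate: Optional[float]
    participant: str = "A1"
    session: int = 1
    run: int = 1

    def __post_init__(self) -> None:
        if self.performance < 0:
            raise ValueError("performance must be nonnegative")
        if not (0.0 <= self.strategy <= 180.0):
            raise ValueError("strategy must lie in [0, 180] degrees")


def summarize_run(run: RunLog) -> ConditionSummary:
    """Collapse one run to its performance / strategy / success-rate summary."""
    if len(run.trials) < 2:
        raise ValueError("need at least 2 trials to summarize a run")
    performance = float(np.mean([t.hsim_k for t in run.trials]))
    deltas = [abs(t.delta_theta_k) for t in run.trials if t.delta_theta_k is not None]
    strategy = float(np.mean(deltas))
    return ConditionSummary(
        condition=run.condition,
        performance=performance,
        strategy=strategy,
        success_rate=run.success_rate,
        participant=run.participant,
        session=run.session,
        run=run.run,
    )


def summaries_to_frame(summaries: Sequence[ConditionSummary]) -> pd.DataFrame:
    """Long-form table of run summaries (one row per participant x run)."""
    return pd.DataFrame(
        {
            "participant": s.participant,
            "session": s.session,
            "run": s.run,
            "condition_id": s.condition.condition_id,
            "feedback_type": s.condition.feedback_type,
            "variability": s.condition.variability,
            "threshold": s.condition.threshold_level,
            "performance": s.performance,
            "strategy": s.strategy,
            "success_rate": s.success_rate,
        }
        for s in summaries
    )


def _check_balanced(data: pd.DataFrame, within: list[str], subject: str) -> None:
    counts = data.groupby([subject, *within], observed=True).size()
    subjects = data[subject].unique()
    levels = [data[w].unique() for w in within]
    expected = {(s, *combo) for s in subjects for combo in itertools.product(*levels)}
    missing = sorted(expected - set(counts.index))
    if missing:
        raise ValueError(f"unbalanced design; missing cells: {missing[:10]}")


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: str | Sequence[str],
    subject: str = "participant",
) -> pd.DataFrame:
    """One- or two-way repeated-measures ANOVA on a long-form table.

    Cells with several runs per participant are averaged first (the subject x
    condition mean is the unit of analysis).  Returns one row per effect (and
    the interaction for two factors) with F, degrees of freedom, uncorrected
    and Greenhouse-Geisser-corrected p-values.
    """
    within = [within] if isinstance(within, str) else list(within)
    if not 1 <= len(within) <= 2:
        raise ValueError("within must name one or two factors")
    _check_balanced(data, within, subject)
    cell = data.groupby([subject, *within], observed=True, as_index=False)[dv].mean()
    # pingouin's melt path can collide with short dv names; use a safe alias
    cell = cell.rename(columns={dv: "_dv_"})
    aov = pg.rm_anova(
        data=cell,
        dv="_dv_",
        within=within if len(within) > 1 else within[0],
        subject=subject,
        correction=True,
        detailed=True,
    )
    out = pd.DataFrame(
        {
            "effect": aov["Source"],
            "F": aov["F"],
            "df1": aov["ddof1"] if "ddof1" in aov else aov["DF"],
            "df2": aov["ddof2"] if "ddof2" in aov else np.nan,
            "p_unc": aov["p_unc"] if "p_unc" in aov else np.nan,
            "p_gg": aov["p_GG_corr"] if "p_GG_corr" in aov else np.nan,
        }
    )
    out = out[out["F"].notna()].reset_index(drop=True)
    if len(within) == 1:
        # detailed one-way output lacks ddof2; it is (n-1)(k-1)
        n = cell[subject].nunique()
        k = cell[within[0]].nunique()
        out.loc[:, "df2"] = (n - 1) * (k - 1)
    return out


def tukey_hsd(
    data: pd.DataFrame,
    dv: str,
    within: str,
    subject: str = "participant",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons for one within-subject factor.

    The error term is the subject-by-level interaction mean square, the
    standard repeated-measures choice; p-values come from the studentized
    range distribution with (k, (n-1)(k-1)) degrees of freedom.  Differences
    are reported as mean(A) - mean(B) with the standard error of a paired
    difference of level means.
    """
    _check_balanced(data, [within], subject)
    cell = data.groupby([subject, within], observed=True, as_index=False)[dv].mean()
    levels = sorted(cell[within].unique())
    k = len(levels)
    if k < 2:
        raise ValueError("need at least 2 levels for pairwise comparisons")
    n = cell[subject].nunique()
    wide = cell.pivot(index=subject, columns=within, values=dv).loc[:, levels]
    y = wide.to_numpy()
    grand = y.mean()
    subj_means = y.mean(axis=1, keepdims=True)
    level_means = y.mean(axis=0, keepdims=True)
    resid = y - subj_means - level_means + grand
    df_err = (n - 1) * (k - 1)
    ms_err = float((resid**2).sum() / df_err)

    rows = []
    se = np.sqrt(2.0 * ms_err / n)
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(level_means[0, i] - level_means[0, j])
            q = abs(diff) / np.sqrt(ms_err / n) if ms_err > 0 else np.inf
            p = float(sps.studentized_range.sf(q, k, df_err)) if ms_err > 0 else 0.0
            if diff == 0.0:
                p = 1.0
            rows.append(
                {
                    "level_a": levels[i],
                    "level_b": levels[j],
                    "diff": diff,
                    "se": float(se),
                    "q": float(q),
                    "p_tukey": p,
                    "significant": p < alpha,
                }
            )
    return pd.DataFrame(rows)
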