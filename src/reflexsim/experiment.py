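"""Full pipeline: simulate agents through the protocol, analyze, validate."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .agents import run_agent
from .config import (
    ExperimentConfig,
    config_hash,
    params_by_condition,
    write_trial_csv,
)
from .environment import RunLog, build_condition_grid, build_protocol
from .stats import rm_anova, summaries_to_frame, summarize_run, tukey_hsd
from .validation import (
    cohort_to_frame,
    fit_lmm,
    generate_synthetic_cohort,
    pearson_correlation,
    predict_performance,
)

__all__ = ["simulate_experiment", "run_experiment", "analyze_logs", "validate_logs", "report"]


def _agent_seed(master_seed: int, agent_index: int) -> int:
    ss = np.random.SeedSequence((int(master_seed), 271, int(agent_index)))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2**31))


def simulate_experiment(config: ExperimentConfig, seed: Optional[int] = None) -> list[RunLog]:
    """Play the three-session protocol with ``n_agents`` seeded agents."""
    master = int(seed) if seed is not None else config.require_seed()
    grid = {c.condition_id: c for c in build_condition_grid()}
    schedule = [
        tuple(grid[cid] for cid in run_order)
        for session in build_protocol(master, config.protocol["runs_per_session"])
        for run_order in session
    ]
    logs: list[RunLog] = []
    for i in range(config.n_agents):
        agent_seed = _agent_seed(master, i)
        logs += run_agent(
            policy=config.policy_config(agent_seed),
            schedule=schedule,
            params_by_condition=params_by_condition(config, agent_seed),
            master_seed=agent_seed,
            trials_per_run=config.protocol["trials_per_condition"],
            fast_step=config.protocol["fast_step"],
            slow_step=config.protocol["slow_step"],
            participant=f"A{i + 1}",
        )
    return logs


def run_experiment(config: ExperimentConfig, out_dir: str | Path, seed: Optional[int] = None) -> Path:
    """Simulate, write the trial CSV and a JSON sidecar; return the directory."""
    master = int(seed) if seed is not None else config.require_seed()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logs = simulate_experiment(config, master)
    write_trial_csv(logs, out / "trials.csv")
    meta = {
        "config": config.to_dict(),
        "config_hash": config_hash(config),
        "seed": master,
        "schedule": build_protocol(master, config.protocol["runs_per_session"]),
        "n_runs": len(logs),
    }
    (out / "metadata.json").write_text(json.dumps(meta, indent=2, default=list) + "\n")
    return out


def analyze_logs(logs: Sequence[RunLog]) -> dict[str, pd.DataFrame]:
    """Run summaries plus the repeated-measures comparisons on them.

    Returns the long-form summary table, per-condition means, and (when the
    design supports them) the variability x feedback-type ANOVA at the
    moderate threshold and pairwise Tukey comparisons of feedback types.
    """
    summaries = summaries_to_frame([summarize_run(l) for l in logs])
    by_condition = (
        summaries.groupby(
            ["condition_id", "feedback_type", "variability", "threshold"], as_index=False
        )
        .agg(
            performance=("performance", "mean"),
            strategy=("strategy", "mean"),
            success_rate=("success_rate", "mean"),
            n_runs=("performance", "size"),
        )
        .sort_values("condition_id", key=lambda s: s.str.lstrip("C").astype(int))
        .reset_index(drop=True)
    )
    out = {"summaries": summaries, "by_condition": by_condition}

    mt = summaries[summaries["threshold"].isin(["MT", "none"])]
    n_participants = summaries["participant"].nunique()
    if n_participants >= 2 and mt["feedback_type"].nunique() == 3:
        try:
            out["anova_var_x_feedback"] = rm_anova(
                mt, dv="performance", within=["variability", "feedback_type"]
            )
            out["tukey_feedback"] = tukey_hsd(mt, dv="performance", within="feedback_type")
        except ValueError:
            pass  # unbalanced ad-hoc logs: summaries alone
    return out


def validate_logs(
    logs: Sequence[RunLog],
    cohort: pd.DataFrame | None = None,
    cohort_seed: int = 0,
) -> dict:
    """Fit the LMM on the simulator's KpKr runs and score cohort predictions."""
    fit = fit_lmm(list(logs))
    if cohort is None:
        cohort = generate_synthetic_cohort(seed=cohort_seed)
    cohort = cohort_to_frame(cohort)
    predicted = predict_performance(fit, cohort)
    per_participant = {}
    for pid, grp in cohort.groupby("participant_id"):
        pred = predict_performance(fit, grp)
        res = pearson_correlation(grp["performance_mean"], pred)
        per_participant[str(pid)] = {
            "r": res.r, "p": res.p, "df": res.df, "n_runs": int(len(grp)),
        }
    overall = pearson_correlation(cohort["performance_mean"], predicted)
    return {
        "lmm": {
            "fixed_intercept": fit.fixed_intercept,
            "fixed_variability_slope": fit.fixed_variability_slope,
            "random_intercept_variance": fit.random_intercept_variance,
            "residual_variance": fit.residual_variance,
            "n_obs": fit.n_obs,
        },
        "n_predictions": int(len(predicted)),
        "overall": {"r": overall.r, "p": overall.p, "df": overall.df},
        "per_participant": per_participant,
    }


def report(artifact_dir: str | Path) -> str:
    """Human-readable per-condition summary of a simulated experiment."""
    from .config import read_trial_csv

    art = Path(artifact_dir)
    logs = read_trial_csv(art / "trials.csv")
    tables = analyze_logs(logs)
    lines = [f"Experiment artifact: {art}", f"Runs: {len(logs)}", ""]
    lines.append(tables["by_condition"].to_string(index=False))
    if "tukey_feedback" in tables:
        lines += ["", "Feedback-type pairwise comparisons (performance):"]
        lines.append(tables["tukey_feedback"].to_string(index=False))
    return "\n".join(lines)
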