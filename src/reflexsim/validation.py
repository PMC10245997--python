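"""Mixed-model validation harness.

The simulator's claim to external validity rests on a linear mixed model
(LMM): run-mean performance regressed on the biological-variability level
(fixed effect) with a participant random intercept,

    performance_ij = b0 + b1 * variability_ij + u_i + e_ij,
    u_i ~ N(0, tau^2),  e_ij ~ N(0, sigma_e^2),

fitted by REML on the combined-feedback (KpKr) conditions.  The fitted model
predicts the run-mean performance of an external cohort from each run's
measured reflex variability, and prediction quality is scored with a Pearson
correlation (df = n - 2; a 24-session x 3-run cohort gives df = 70).

No external dataset ships with the package; ``generate_synthetic_cohort``
emits a cohort in the same layout (participants x 24 sessions x 3 runs) with
a known variability slope, so the whole harness runs self-contained and the
fitting code can be checked by parameter recovery.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

from .environment import RunLog
from .stats import ConditionSummary, summarize_run

__all__ = [
    "CohortRun",
    "LMMFit",
    "PearsonResult",
    "cohort_to_frame",
    "runs_to_lmm_frame",
    "fit_lmm",
    "predict_performance",
    "pearson_correlation",
    "generate_synthetic_cohort",
    "COHORT_COLUMNS",
]

COHORT_COLUMNS = [
    "participant_id",
    "group",
    "session",
    "run",
    "measured_variability",
    "performance_mean",
]

#: Sessions x runs layout of the external conditioning cohort being emulated.
N_SESSIONS = 24
RUNS_PER_SESSION = 3


@dataclass(frozen=True)
class CohortRun:
    """One run of a (real-format or synthetic) conditioning cohort."""

    participant_id: str
    session: int
    run: int
    measured_variability: float
    performance_mean: float
    group: str = "healthy"

    def __post_init__(self) -> None:
        if self.measured_variability < 0:
            raise ValueError("measured_variability must be nonnegative")


@dataclass(frozen=True)
class LMMFit:
    """REML estimates of the variability -> performance mixed model."""

    fixed_intercept: float
    fixed_variability_slope: float
    random_intercept_variance: float
    residual_variance: float
    random_intercepts: dict[str, float]
    slope_se: float
    slope_ci: tuple[float, float]
    n_obs: int

    def __post_init__(self) -> None:
        if self.random_intercept_variance < 0 or self.residual_variance < 0:
            raise ValueError("variance components must be nonnegative")


class PearsonResult(NamedTuple):
    r: float
    p: float
    df: int


def cohort_to_frame(runs: Sequence[CohortRun] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(runs, pd.DataFrame):
        missing = [c for c in ("participant_id", "measured_variability", "performance_mean") if c not in runs]
        if missing:
            raise ValueError(f"cohort frame lacks columns: {missing}")
        return runs.copy()
    return pd.DataFrame(
        {
            "participant_id": r.participant_id,
            "group": r.group,
            "session": r.session,
            "run": r.run,
            "measured_variability": r.measured_variability,
            "performance_mean": r.performance_mean,
        }
        for r in runs
    )


def runs_to_lmm_frame(logs: Sequence[RunLog]) -> pd.DataFrame:
    """Run-level modelling table from simulator logs of the KpKr conditions.

    Each KpKr run contributes one row: participant, the variability variance
    sigma^2 of its condition, and the run-mean performance.
    """
    rows = []
    for log in logs:
        if log.condition.feedback_type != "KpKr":
            continue
        s: ConditionSummary = summarize_run(log)
        rows.append(
            {
                "participant_id": s.participant,
                "measured_variability": log.condition.sigma2,
                "performance_mean": s.performance,
            }
        )
    if not rows:
        raise ValueError("no KpKr run logs supplied")
    return pd.DataFrame(rows)


def fit_lmm(data: Sequence[CohortRun] | Sequence[RunLog] | pd.DataFrame, reml: bool = True) -> LMMFit:
    """Fit performance ~ variability with a participant random intercept.

    Accepts a cohort table/record list or simulator run logs (their KpKr runs
    are extracted).  Needs at least two participants and two distinct
    variability values; with a degenerate (zero) random-effect variance the
    fixed slope collapses to the ordinary least-squares slope.
    """
    if len(data) and isinstance(data[0] if not isinstance(data, pd.DataFrame) else None, RunLog):
        df = runs_to_lmm_frame(data)  # type: ignore[arg-type]
    else:
        df = cohort_to_frame(data)
    if df["participant_id"].nunique() < 2:
        raise ValueError("random intercept unidentifiable with a single participant")
    if df["measured_variability"].nunique() < 2:
        raise ValueError("need at least two distinct variability values")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary (zero-variance) fits warn
        model = smf.mixedlm(
            "performance_mean ~ measured_variability",
            data=df,
            groups=df["participant_id"],
        )
        res = model.fit(reml=reml)

    try:
        blups = {
            str(k): float(np.asarray(v)[0]) for k, v in res.random_effects.items()
        }
    except ValueError:
        # singular (zero-variance) random-effect covariance: BLUPs are all 0
        blups = {str(k): 0.0 for k in df["participant_id"].unique()}

    ci = res.conf_int().loc["measured_variability"]
    return LMMFit(
        fixed_intercept=float(res.fe_params["Intercept"]),
        fixed_variability_slope=float(res.fe_params["measured_variability"]),
        random_intercept_variance=max(float(np.asarray(res.cov_re)[0, 0]), 0.0),
        residual_variance=float(res.scale),
        random_intercepts=blups,
        slope_se=float(res.bse["measured_variability"]),
        slope_ci=(float(ci[0]), float(ci[1])),
        n_obs=int(len(df)),
    )


def predict_performance(
    fit: LMMFit,
    runs: Sequence[CohortRun] | pd.DataFrame,
    include_random: bool = False,
) -> np.ndarray:
    """Predicted run-mean performance for each cohort run.

    Population-level by default (fixed effects only, appropriate for new
    participants); ``include_random=True`` adds the estimated random
    intercept for participants seen during fitting.
    """
    df = cohort_to_frame(runs)
    v = df["measured_variability"].to_numpy(dtype=float)
    if (v < 0).any():
        raise ValueError("measured_variability must be nonnegative")
    pred = fit.fixed_intercept + fit.fixed_variability_slope * v
    if include_random:
        pred = pred + np.array(
            [fit.random_intercepts.get(str(p), 0.0) for p in df["participant_id"]]
        )
    return pred


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> PearsonResult:
    """Product-moment correlation with a two-sided t-based p (df = n - 2)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("x and y must be equal-length 1-D with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant sequence")
    r, p = sps.pearsonr(x, y)
    return PearsonResult(r=float(r), p=float(p), df=int(x.size - 2))


def generate_synthetic_cohort(
    n_participants: int = 7,
    effect_size: float = 0.228,
    random_sd: float = 0.03,
    residual_sd: float = 0.05,
    seed: int = 0,
    intercept: float = 0.55,
    n_healthy: int = 5,
) -> pd.DataFrame:
    """Synthetic conditioning cohort in the external-data layout.

    Each participant contributes 24 sessions x 3 runs = 72 runs.  Per-run
    measured variability is uniform on [0.25, 0.75] (the simulator's low/high
    variance endpoints); run-mean performance follows the mixed model
    ``intercept + effect_size * variability + participant intercept + noise``.
    The default slope 0.228 makes the expected performance gap between the
    variance endpoints 0.114, the low-vs-high gap the simulator is built
    around.  Participants beyond ``n_healthy`` are tagged "stroke" — a label
    passthrough only, with no separate generative mechanism.
    """
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    if random_sd < 0 or residual_sd < 0:
        raise ValueError("standard deviations must be nonnegative")
    rng = np.random.Generator(np.random.PCG64(np.random.SeedSequence((int(seed), 409))))
    rows = []
    for i in range(n_participants):
        healthy = i < n_healthy
        pid = f"H{i + 1}" if healthy else f"S{i + 1 - n_healthy}"
        u = rng.normal(0.0, random_sd)
        for session in range(1, N_SESSIONS + 1):
            for run in range(1, RUNS_PER_SESSION + 1):
                v = rng.uniform(0.25, 0.75)
                perf = intercept + effect_size * v + u + rng.normal(0.0, residual_sd)
                rows.append(
                    {
                        "participant_id": pid,
                        "group": "healthy" if healthy else "stroke",
                        "session": session,
                        "run": run,
                        "measured_variability": v,
                        "performance_mean": perf,
                    }
                )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)
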