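"""Experiment configuration: schema, YAML round-trip, hashing, trial-log IO."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import pandas as pd
import yaml

from .agents import PolicyConfig
from .environment import (
    THRESHOLDS,
    TRIALS_PER_RUN,
    Condition,
    RunLog,
    TrialRecord,
    build_condition_grid,
)
from .reflex import HReflexParams

__all__ = [
    "ExperimentConfig",
    "default_config",
    "load_config",
    "save_config",
    "config_hash",
    "params_for_condition",
    "write_trial_csv",
    "read_trial_csv",
    "TRIAL_CSV_COLUMNS",
]

TRIAL_CSV_COLUMNS = [
    "participant",
    "session",
    "run",
    "condition_id",
    "feedback_type",
    "variability",
    "threshold",
    "k",
    "theta",
    "theta_tar",
    "beta",
    "hsim",
    "success",
    "delta_theta",
    "n_keypresses",
    "seed",
]

_MODEL_KEYS = {"gain_g", "intercept_c0", "mu", "noise_aN", "n_samples"}
_PROTOCOL_KEYS = {"trials_per_condition", "runs_per_session", "fast_step", "slow_step"}
_POLICY_KEYS = {"policy_name", "exploration_step", "step_decay"}


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to reproduce a full simulated experiment."""

    model: dict[str, Any] = field(
        default_factory=lambda: {
            "gain_g": 0.5 / 180.0,
            "intercept_c0": 0.5,
            "mu": 1.0,
            "noise_aN": 0.05,
            "n_samples": 100,
        }
    )
    thresholds: dict[str, float] = field(default_factory=lambda: dict(THRESHOLDS))
    protocol: dict[str, Any] = field(
        default_factory=lambda: {
            "trials_per_condition": TRIALS_PER_RUN,
            "runs_per_session": 10,
            "fast_step": 10.0,
            "slow_step": 1.0,
        }
    )
    policy: dict[str, Any] = field(
        default_factory=lambda: {
            "policy_name": "hybrid",
            "exploration_step": 20.0,
            "step_decay": 0.95,
        }
    )
    seed: Optional[int] = None
    n_agents: int = 7

    def __post_init__(self) -> None:
        problems = []
        problems += [f"model.{k}" for k in set(self.model) - _MODEL_KEYS]
        problems += [f"model.{k} (missing)" for k in _MODEL_KEYS - set(self.model)]
        problems += [f"thresholds.{k}" for k in set(self.thresholds) - set(THRESHOLDS)]
        problems += [f"protocol.{k}" for k in set(self.protocol) - _PROTOCOL_KEYS]
        problems += [f"policy.{k}" for k in set(self.policy) - _POLICY_KEYS]
        if problems:
            raise ValueError(f"invalid config keys: {sorted(problems)}")
        if self.n_agents < 1:
            raise ValueError("n_agents must be >= 1")

    def to_dict(self) -> dict[str, Any]:
        return {
            "model": dict(self.model),
            "thresholds": dict(self.thresholds),
            "protocol": dict(self.protocol),
            "policy": dict(self.policy),
            "seed": self.seed,
            "n_agents": self.n_agents,
        }

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "ExperimentConfig":
        known = {"model", "thresholds", "protocol", "policy", "seed", "n_agents"}
        extra = set(d) - known
        if extra:
            raise ValueError(f"invalid config keys: {sorted(extra)}")
        return cls(**d)

    def policy_config(self, seed: int) -> PolicyConfig:
        return PolicyConfig(rng_seed=seed, **self.policy)

    def require_seed(self) -> int:
        """The master seed; set in the config or passed explicitly, never implicit."""
        if self.seed is None:
            raise ValueError("no seed configured; pass --seed or set seed in the config")
        return int(self.seed)


def default_config() -> ExperimentConfig:
    return ExperimentConfig()


def load_config(path: str | Path) -> ExperimentConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} is not a mapping")
    return ExperimentConfig.from_dict(raw)


def save_config(config: ExperimentConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


def config_hash(config: ExperimentConfig) -> str:
    """Stable short hash of the canonicalized config."""
    canon = json.dumps(config.to_dict(), sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()[:12]


def params_for_condition(config: ExperimentConfig, condition: Condition, seed: int) -> HReflexParams:
    return HReflexParams(sigma2=condition.sigma2, rng_seed=seed, **config.model)


def params_by_condition(config: ExperimentConfig, seed: int) -> dict[str, HReflexParams]:
    return {
        c.condition_id: params_for_condition(config, c, seed)
        for c in build_condition_grid()
    }


def _fmt(x: Any) -> str:
    if x is None:
        return ""
    if isinstance(x, bool):
        return str(int(x))
    if isinstance(x, float):
        return repr(x)
    return str(x)


def write_trial_csv(logs: list[RunLog], path: str | Path) -> None:
    """One row per trial; absent success / delta fields are left empty."""
    lines = [",".join(TRIAL_CSV_COLUMNS)]
    for log in logs:
        c = log.condition
        for t in log.trials:
            lines.append(
                ",".join(
                    _fmt(v)
                    for v in (
                        log.participant,
                        log.session,
                        log.run,
                        c.condition_id,
                        c.feedback_type,
                        c.variability,
                        c.threshold_level,
                        t.k,
                        t.theta_k,
                        t.theta_tar,
                        t.beta_k,
                        t.hsim_k,
                        t.success,
                        t.delta_theta_k,
                        t.n_keypresses,
                        log.seed,
                    )
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_trial_csv(path: str | Path) -> list[RunLog]:
    """Parse a trial-log CSV back into the exact run logs written."""
    df = pd.read_csv(path, dtype={"success": "object"}, float_precision="round_trip")
    logs: list[RunLog] = []
    keys = ["participant", "session", "run", "condition_id"]
    for (participant, session, run, cid), grp in df.groupby(keys, sort=False):
        first = grp.iloc[0]
        condition = Condition(
            condition_id=cid,
            feedback_type=first["feedback_type"],
            variability=first["variability"],
            threshold_level=str(first["threshold"]),
        )
        trials = []
        for _, row in grp.sort_values("k").iterrows():
            success = None if pd.isna(row["success"]) else bool(int(float(row["success"])))
            delta = None if pd.isna(row["delta_theta"]) else float(row["delta_theta"])
            trials.append(
                TrialRecord(
                    k=int(row["k"]),
                    theta_k=float(row["theta"]),
                    theta_tar=float(row["theta_tar"]),
                    beta_k=float(row["beta"]),
                    hsim_k=float(row["hsim"]),
                    success=success,
                    delta_theta_k=delta,
                    n_keypresses=int(row["n_keypresses"]),
                )
            )
        successes = [t.success for t in trials if t.success is not None]
        score = sum(1 if s else -1 for s in successes) if successes else 0
        rate = sum(successes) / len(successes) if successes else None
        logs.append(
            RunLog(
                condition=condition,
                trials=trials,
                seed=int(first["seed"]),
                score=score,
                success_rate=rate,
                participant=str(participant),
                session=int(session),
                run=int(run),
            )
        )
    return logs
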