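"""Agent policies that stand in for human players.

Real participants supply the explicit search behaviour the game measures;
these policies are simple stand-ins so the environment can be exercised
end-to-end and its outcome statistics stress-tested.  They are deliberately
plain search heuristics, not models fitted to human data:

* ``random_walk`` — blind exploration, a +/- step each trial.
* ``hill_climb`` — gradient-free descent on the bar height (needs Kp or
  KpKr feedback); keeps direction while the bar falls, reverses and halves
  its step when it rises.
* ``win_stay_lose_shift`` — binary-feedback heuristic (needs Kr or KpKr):
  stay put after a success, jump after a failure.
* ``hybrid`` — uses whatever the feedback exposes: hill-climbing on bar
  height when it is visible, anchored in place after a success, and pure
  win-stay/lose-shift when only the binary result is shown.

All policies decay their exploration step geometrically over trials
(coarse-to-fine search) and are fully seeded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .environment import (
    TRIALS_PER_RUN,
    Condition,
    DialState,
    FeedbackSignal,
    RunLog,
    RunState,
    TrialRecord,
)
from .reflex import HReflexParams, signed_delta

__all__ = ["PolicyConfig", "decide", "target_to_keys", "run_agent", "POLICY_NAMES"]

POLICY_NAMES = ("random_walk", "hill_climb", "win_stay_lose_shift", "hybrid")


@dataclass(frozen=True)
class PolicyConfig:
    policy_name: str = "hill_climb"
    exploration_step: float = 20.0
    step_decay: float = 0.95
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.policy_name not in POLICY_NAMES:
            raise ValueError(f"unknown policy {self.policy_name!r}")
        if self.exploration_step <= 0:
            raise ValueError("exploration_step must be positive")
        if not (0.0 < self.step_decay <= 1.0):
            raise ValueError("step_decay must lie in (0, 1]")


def _requires(policy: str, condition: Condition) -> None:
    fb = condition.feedback_type
    if policy == "hill_climb" and fb == "Kr":
        raise ValueError("hill_climb needs a visible bar height; unavailable under Kr")
    if policy == "win_stay_lose_shift" and fb == "Kp":
        raise ValueError("win_stay_lose_shift needs success information; unavailable under Kp")


def _last_direction(history: list[tuple[TrialRecord, FeedbackSignal]]) -> float:
    for rec, _ in reversed(history):
        if rec.delta_theta_k is not None and rec.delta_theta_k != 0.0:
            return 1.0 if rec.delta_theta_k > 0 else -1.0
    return 0.0


def decide(
    policy: PolicyConfig,
    condition: Condition,
    history: list[tuple[TrialRecord, FeedbackSignal]],
    current_theta: float,
    rng: np.random.Generator,
    step_override: float | None = None,
) -> float:
    """Choose the dial angle to commit on the next trial.

    ``history`` pairs each past trial record with the feedback the player
    saw.  The per-trial exploration step is ``exploration_step`` decayed by
    ``step_decay`` per committed trial (hill-climbers additionally halve it
    on overshoot, tracked by the caller through ``step_override``).
    """
    _requires(policy.policy_name, condition)
    k = len(history)
    step = step_override if step_override is not None else policy.exploration_step * policy.step_decay**k
    if k == 0:
        return current_theta % 360.0

    name = policy.policy_name
    last_rec, last_fb = history[-1]

    if name == "random_walk":
        sign = 1.0 if rng.random() < 0.5 else -1.0
        return (current_theta + sign * step) % 360.0

    bar_visible = condition.feedback_type in ("Kp", "KpKr")
    if name == "win_stay_lose_shift" or (name == "hybrid" and not bar_visible):
        if last_rec.success:
            return current_theta % 360.0
        sign = 1.0 if rng.random() < 0.5 else -1.0
        return (current_theta + sign * step) % 360.0

    # hill_climb / hybrid: move along the bar-height gradient.
    if name == "hybrid" and last_fb.success_shown and last_rec.success:
        return current_theta % 360.0
    if k == 1:
        sign = 1.0 if rng.random() < 0.5 else -1.0
        return (current_theta + sign * step) % 360.0
    prev_fb = history[-2][1]
    direction = _last_direction(history)
    if direction == 0.0:
        direction = 1.0 if rng.random() < 0.5 else -1.0
    if last_fb.bar_height > prev_fb.bar_height:
        direction = -direction  # bar rose: we walked away from the target
    # ties (equal heights) keep the previous direction
    return (current_theta + direction * step) % 360.0


def target_to_keys(dial: DialState, target_theta: float) -> list[str]:
    """Greedy fast-then-slow keypress sequence reaching ``target_theta``.

    The requested change is rounded to the nearest multiple of the slow step,
    so any target on the slow-step grid is reached exactly (mod 360).
    """
    delta = signed_delta(target_theta, dial.theta)
    n_slow_total = round(abs(delta) / dial.slow_step)
    if n_slow_total == 0:
        return []
    cw = delta > 0
    per_fast = round(dial.fast_step / dial.slow_step)
    n_fast, n_slow = divmod(n_slow_total, per_fast) if per_fast > 0 else (0, n_slow_total)
    keys = ["fast_cw" if cw else "fast_ccw"] * n_fast
    keys += ["slow_cw" if cw else "slow_ccw"] * n_slow
    return keys


def _session_of(condition_id: str) -> int:
    n = int(condition_id[1:])
    return 1 if n <= 4 else (2 if n <= 8 else 3)


def run_agent(
    policy: PolicyConfig,
    schedule: list[tuple[Condition, ...]] | list[Condition],
    params_by_condition: dict[str, HReflexParams],
    master_seed: int,
    trials_per_run: int = TRIALS_PER_RUN,
    fast_step: float = 10.0,
    slow_step: float = 1.0,
    participant: str = "A1",
) -> list[RunLog]:
    """Play every condition run in ``schedule`` and return the run logs.

    ``schedule`` is either a flat list of conditions (one run each) or a list
    of runs, each an ordered tuple of conditions.  The hidden target and the
    initial dial angle are drawn uniformly per run from seeded substreams;
    everything is reproducible from ``master_seed``.
    """
    if schedule and isinstance(schedule[0], Condition):
        schedule = [(c,) for c in schedule]  # type: ignore[list-item]

    # Hill-climbers halve their step on overshoot; track it per run.
    logs: list[RunLog] = []
    for run_idx, run_conditions in enumerate(schedule):
        for cond_idx, condition in enumerate(run_conditions):
            setup = np.random.Generator(
                np.random.PCG64(
                    np.random.SeedSequence((int(master_seed), 131, run_idx, cond_idx))
                )
            )
            theta_tar = float(setup.uniform(0.0, 360.0))
            theta0 = float(setup.uniform(0.0, 360.0))
            trial_seed = int(setup.integers(0, 2**31))
            policy_rng = np.random.Generator(
                np.random.PCG64(
                    np.random.SeedSequence(
                        (int(policy.rng_seed), int(master_seed), 557, run_idx, cond_idx)
                    )
                )
            )
            params = params_by_condition[condition.condition_id]
            state = RunState(
                condition=condition,
                params=params,
                theta_tar=theta_tar,
                seed=trial_seed,
                dial=DialState(theta=theta0, fast_step=fast_step, slow_step=slow_step),
                max_trials=trials_per_run,
            )
            history: list[tuple[TrialRecord, FeedbackSignal]] = []
            step = policy.exploration_step
            for _ in range(trials_per_run):
                target = decide(
                    policy, condition, history, state.dial.theta, policy_rng,
                    step_override=max(step, slow_step),
                )
                for key in target_to_keys(state.dial, target):
                    state.press(key)
                rec, fb = state.commit()
                if (
                    policy.policy_name in ("hill_climb", "hybrid")
                    and len(history) >= 2
                    and fb.bar_height > history[-1][1].bar_height
                ):
                    step = max(step * 0.5, slow_step)
                step *= policy.step_decay
                history.append((rec, fb))
            logs.append(
                state.to_log(
                    participant=participant,
                    session=_session_of(condition.condition_id),
                    run=run_idx + 1,
                )
            )
    return logs
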