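"""The conditioning game: conditions, protocol, dial, trials and feedback.

A run is 35 committed decisions ("trials") under one condition.  The player
rotates a circular dial with discrete fast/slow keypresses, commits with a
select action, and receives feedback computed from the simulated H-reflex at
the committed angle.  Feedback comes in three flavours:

* ``Kp`` (knowledge of performance): a blue bar whose height is the signal
  peak-to-peak magnitude; no success/failure information.
* ``Kr`` (knowledge of results): a fixed-height bar that turns green when the
  magnitude falls below the reward threshold and red otherwise; the magnitude
  itself is hidden.
* ``KpKr``: proportional bar height with Kr colouring.

Ten conditions cross feedback type with low/high biological variability, with
three reward thresholds (easy/moderate/difficult) crossed in under Kr only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .reflex import (
    SIGMA2_HV,
    SIGMA2_LV,
    HReflexParams,
    signed_delta,
    simulate_hreflex,
    trial_rng,
)

__all__ = [
    "THRESHOLDS",
    "FIXED_BAR_HEIGHT",
    "Condition",
    "DialState",
    "TrialRecord",
    "FeedbackSignal",
    "RunLog",
    "RunState",
    "build_condition_grid",
    "build_protocol",
    "apply_key",
    "render_feedback",
    "commit_trial",
    "TRIALS_PER_RUN",
]

#: Reward thresholds (44th/66th/77th percentile of unconditioned reflexes).
THRESHOLDS = {"ET": 0.46, "MT": 0.7, "DT": 0.96}

#: Bar height shown under Kr feedback, which must not leak the magnitude.
FIXED_BAR_HEIGHT = 0.5

TRIALS_PER_RUN = 35

_FEEDBACK_TYPES = ("Kp", "Kr", "KpKr")
_VARIABILITY = {"LV": SIGMA2_LV, "HV": SIGMA2_HV}
_KEYS = ("fast_ccw", "slow_ccw", "fast_cw", "slow_cw")


@dataclass(frozen=True)
class Condition:
    """One cell of the factorial design (feedback x variability x threshold)."""

    condition_id: str
    feedback_type: str
    variability: str
    threshold_level: str

    def __post_init__(self) -> None:
        if self.feedback_type not in _FEEDBACK_TYPES:
            raise ValueError(f"unknown feedback_type {self.feedback_type!r}")
        if self.variability not in _VARIABILITY:
            raise ValueError(f"unknown variability {self.variability!r}")
        if self.feedback_type == "Kr" and self.threshold_level not in THRESHOLDS:
            raise ValueError("Kr conditions need a threshold level (ET/MT/DT)")
        if self.feedback_type == "KpKr" and self.threshold_level != "MT":
            raise ValueError("KpKr conditions run at the moderate threshold")
        if self.feedback_type == "Kp" and self.threshold_level != "none":
            raise ValueError("Kp conditions carry no displayed threshold")

    @property
    def sigma2(self) -> float:
        return _VARIABILITY[self.variability]

    @property
    def threshold_value(self) -> Optional[float]:
        """Reward threshold magnitude, or None for pure Kp feedback."""
        return THRESHOLDS.get(self.threshold_level)


@dataclass(frozen=True)
class DialState:
    """Circular dial position with discrete fast/slow step sizes (degrees)."""

    theta: float = 0.0
    fast_step: float = 10.0
    slow_step: float = 1.0

    def __post_init__(self) -> None:
        if self.fast_step <= 0 or self.slow_step <= 0:
            raise ValueError("step sizes must be positive")
        object.__setattr__(self, "theta", float(self.theta) % 360.0)


@dataclass(frozen=True)
class TrialRecord:
    """One committed decision and its realized feedback signal."""

    k: int
    theta_k: float
    theta_tar: float
    beta_k: float
    hsim_k: float
    success: Optional[bool]
    delta_theta_k: Optional[float]
    n_keypresses: int = 0


@dataclass(frozen=True)
class FeedbackSignal:
    """What the player actually sees after committing a trial."""

    bar_height: float
    bar_color: str
    success_shown: bool


@dataclass
class RunLog:
    """Ordered trial records for one condition run plus metadata."""

    condition: Condition
    trials: list[TrialRecord]
    seed: int
    score: int
    success_rate: Optional[float]
    participant: str = "A1"
    session: int = 1
    run: int = 1


def build_condition_grid() -> list[Condition]:
    """The ten-condition factorial grid, ids C1-C10.

    Kp x {LV, HV} (C1-C2), Kr x {ET, MT, DT} x {LV, HV} (C3-C8) and
    KpKr at MT x {LV, HV} (C9-C10).
    """
    grid = [
        Condition("C1", "Kp", "LV", "none"),
        Condition("C2", "Kp", "HV", "none"),
        Condition("C3", "Kr", "LV", "ET"),
        Condition("C4", "Kr", "HV", "ET"),
        Condition("C5", "Kr", "LV", "MT"),
        Condition("C6", "Kr", "HV", "MT"),
        Condition("C7", "Kr", "LV", "DT"),
        Condition("C8", "Kr", "HV", "DT"),
        Condition("C9", "KpKr", "LV", "MT"),
        Condition("C10", "KpKr", "HV", "MT"),
    ]
    return grid


_SESSION_SPLIT = (("C1", "C2", "C3", "C4"), ("C5", "C6", "C7", "C8"), ("C9", "C10"))


def build_protocol(master_seed: int, runs_per_session: int = 10) -> list[list[tuple[str, ...]]]:
    """Three-session schedule of pseudo-randomized condition orderings.

    Session 1 cycles C1-C4, session 2 C5-C8, session 3 C9-C10; each session
    holds ``runs_per_session`` runs and within each run the condition order is
    a seeded permutation, constrained so no ordering repeats on consecutive
    runs.  Returns, per session, a list of condition-id tuples (one per run).
    """
    schedule: list[list[tuple[str, ...]]] = []
    for s_idx, conds in enumerate(_SESSION_SPLIT):
        rng = np.random.Generator(
            np.random.PCG64(np.random.SeedSequence((int(master_seed), 977, s_idx)))
        )
        runs: list[tuple[str, ...]] = []
        prev: Optional[tuple[str, ...]] = None
        for _ in range(runs_per_session):
            order = tuple(np.array(conds)[rng.permutation(len(conds))])
            while order == prev:
                order = tuple(np.array(conds)[rng.permutation(len(conds))])
            runs.append(order)
            prev = order
        schedule.append(runs)
    return schedule


def apply_key(dial: DialState, key: str) -> DialState:
    """One discrete dial move; clockwise increases theta, wrapped mod 360."""
    if key not in _KEYS:
        raise ValueError(f"unknown key {key!r}; expected one of {_KEYS}")
    step = dial.fast_step if key.startswith("fast") else dial.slow_step
    sign = 1.0 if key.endswith("cw") and not key.endswith("ccw") else -1.0
    return replace(dial, theta=(dial.theta + sign * step) % 360.0)


def render_feedback(condition: Condition, hsim: float) -> FeedbackSignal:
    """Map a realized signal magnitude to the on-screen feedback.

    Success is strict: the bar turns green only when the magnitude is below
    the threshold; landing exactly on the threshold is a failure.
    """
    if hsim < 0:
        raise ValueError("hsim must be nonnegative")
    if condition.feedback_type == "Kp":
        return FeedbackSignal(bar_height=float(hsim), bar_color="blue", success_shown=False)
    thr = condition.threshold_value
    if thr is None:
        raise ValueError(f"{condition.condition_id}: Kr/KpKr feedback needs a threshold")
    color = "green" if hsim < thr else "red"
    height = float(hsim) if condition.feedback_type == "KpKr" else FIXED_BAR_HEIGHT
    return FeedbackSignal(bar_height=height, bar_color=color, success_shown=True)


@dataclass
class RunState:
    """Mutable state of one condition run in progress."""

    condition: Condition
    params: HReflexParams
    theta_tar: float
    seed: int
    dial: DialState = field(default_factory=DialState)
    trials: list[TrialRecord] = field(default_factory=list)
    feedback: list[FeedbackSignal] = field(default_factory=list)
    score: int = 0
    max_trials: int = TRIALS_PER_RUN
    _presses_this_trial: int = 0

    def press(self, key: str) -> None:
        self.dial = apply_key(self.dial, key)
        self._presses_this_trial += 1

    def commit(self) -> tuple[TrialRecord, FeedbackSignal]:
        return commit_trial(self)

    @property
    def complete(self) -> bool:
        return len(self.trials) >= self.max_trials

    def to_log(self, participant: str = "A1", session: int = 1, run: int = 1) -> RunLog:
        successes = [t.success for t in self.trials if t.success is not None]
        rate = (sum(successes) / len(successes)) if successes else None
        return RunLog(
            condition=self.condition,
            trials=list(self.trials),
            seed=self.seed,
            score=self.score,
            success_rate=rate,
            participant=participant,
            session=session,
            run=run,
        )


def commit_trial(state: RunState) -> tuple[TrialRecord, FeedbackSignal]:
    """Commit the current dial position: simulate, render, log, score.

    Success (when the condition defines it) adds one point, failure removes
    one.  Pure Kp trials carry no success flag and leave the score untouched.
    """
    if state.complete:
        raise RuntimeError(f"run already holds {state.max_trials} trials")
    k = len(state.trials) + 1
    rng = trial_rng(state.seed, k)
    sig = simulate_hreflex(state.dial.theta, state.theta_tar, state.params, rng)
    fb = render_feedback(state.condition, sig.pkpk)

    if state.condition.feedback_type == "Kp":
        success: Optional[bool] = None
    else:
        success = sig.pkpk < state.condition.threshold_value
        state.score += 1 if success else -1

    delta = None
    if state.trials:
        delta = signed_delta(state.dial.theta, state.trials[-1].theta_k)

    rec = TrialRecord(
        k=k,
        theta_k=state.dial.theta,
        theta_tar=state.theta_tar,
        beta_k=sig.beta_drawn,
        hsim_k=sig.pkpk,
        success=success,
        delta_theta_k=delta,
        n_keypresses=state._presses_this_trial,
    )
    state.trials.append(rec)
    state.feedback.append(fb)
    state._presses_this_trial = 0
    return rec, fb
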