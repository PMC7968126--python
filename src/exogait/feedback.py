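"""Real-time step-length biofeedback: estimation, target, scoring.

The device estimates each step length from consecutive foot-contact
times on a treadmill at a known fixed belt speed,

    step_length_n = walking_speed * (t_n - t_{n-1}),

where ``t_n`` is the contact time of the n-th step (sides alternate, so
each interval spans one step).  The visual interface shows, per side,
the moving average of that side's last two steps, refreshed every two
strides, with a horizontal bar at the target step length — set 10%
above the participant's baseline mean.  On each refresh, one point is
scored if the average of the most recent left and right step estimates
strictly exceeds the target.

"Average length of the last two steps" is read as the mean of the most
recent left and right estimate (one stride); for strictly alternating
gait this coincides with the last two consecutive steps regardless of
side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .events import FootContactEvent, detect_events_fsr, merge_events
from .synth import GaitTrial

__all__ = [
    "StepRecord",
    "SessionConfig",
    "BiofeedbackState",
    "estimate_step_length",
    "compute_target",
    "step_feedback_update",
    "run_session",
]


def estimate_step_length(speed: float, t_prev: float, t_curr: float) -> float:
    """Step length in meters from two consecutive contact times."""
    if speed <= 0:
        raise ValueError(f"walking speed must be positive, got {speed}")
    if not t_curr > t_prev:
        raise ValueError(
            f"out-of-order contact events: t_curr={t_curr} <= t_prev={t_prev}"
        )
    return speed * (t_curr - t_prev)


def compute_target(baseline_mean_step_m: float, target_factor: float = 1.10) -> float:
    """Target step length: baseline mean scaled by the target factor
    (default +10%)."""
    if baseline_mean_step_m <= 0:
        raise ValueError(
            f"baseline mean step length must be positive, got {baseline_mean_step_m}"
        )
    if target_factor <= 0:
        raise ValueError(f"target_factor must be positive, got {target_factor}")
    return baseline_mean_step_m * target_factor


@dataclass(frozen=True)
class StepRecord:
    """One estimated step: index, striking side, contact time, length."""

    index: int
    side: str
    contact_time_s: float
    est_length_m: float

    def __post_init__(self) -> None:
        if self.est_length_m <= 0:
            raise ValueError("est_length_m must be positive")


@dataclass(frozen=True)
class SessionConfig:
    """Fixed parameters of one biofeedback session."""

    walking_speed: float
    baseline_mean_step_m: float
    target_factor: float = 1.10
    update_every_strides: int = 2
    window_steps: int = 2

    def __post_init__(self) -> None:
        if self.walking_speed <= 0:
            raise ValueError("walking_speed must be positive")
        if self.baseline_mean_step_m <= 0:
            raise ValueError("baseline_mean_step_m must be positive")
        if self.target_factor <= 0:
            raise ValueError("target_factor must be positive")
        if self.update_every_strides < 1 or self.window_steps < 1:
            raise ValueError("cadence parameters must be >= 1")

    @property
    def target_m(self) -> float:
        return compute_target(self.baseline_mean_step_m, self.target_factor)


@dataclass(frozen=True)
class BiofeedbackState:
    """Interface state after processing one step event.

    ``display`` positions are normalized by twice the target so the
    target bar sits mid-screen; they are cosmetic but logged for audit.
    ``refreshed`` marks the states at which the display (and score) were
    updated — every ``update_every_strides`` strides.
    """

    time_s: float
    n_steps: int
    target_m: float
    left_avg_m: float = float("nan")
    right_avg_m: float = float("nan")
    score: int = 0
    hit: bool = False
    refreshed: bool = False
    last_update_stride: int = 0
    display: dict = field(default_factory=dict)


def _side_average(history: list[float], window: int) -> float:
    if not history:
        return float("nan")
    return float(np.mean(history[-window:]))


def step_feedback_update(
    state: BiofeedbackState,
    config: SessionConfig,
    step: StepRecord,
    left_history: list[float],
    right_history: list[float],
) -> BiofeedbackState:
    """Advance the interface state with one newly completed step.

    ``left_history``/``right_history`` are the session's per-side
    estimate lists *including* ``step`` (most recent last).  The display
    refreshes only when the completed-stride count reaches the next
    multiple of ``update_every_strides``; a refresh scores one point if
    the mean of the most recent left and right estimates strictly
    exceeds the target.
    """
    if step.side not in ("left", "right"):
        raise ValueError(f"unknown side {step.side!r}")
    n = state.n_steps + 1
    strides = n // 2
    refresh = (
        strides > state.last_update_stride
        and strides % config.update_every_strides == 0
    )
    left_avg = _side_average(left_history, config.window_steps)
    right_avg = _side_average(right_history, config.window_steps)
    score = state.score
    hit = state.hit
    last_update = state.last_update_stride
    if refresh:
        last_l = left_history[-1] if left_history else float("nan")
        last_r = right_history[-1] if right_history else float("nan")
        pair_mean = 0.5 * (last_l + last_r)
        hit = bool(np.isfinite(pair_mean) and pair_mean > config.target_m)
        if hit:
            score += 1
        last_update = strides
    norm = 2.0 * config.target_m
    display = {
        "left_pos": left_avg / norm if np.isfinite(left_avg) else 0.0,
        "right_pos": right_avg / norm if np.isfinite(right_avg) else 0.0,
        "bar_pos": 0.5,
        "hit": hit,
    }
    return BiofeedbackState(
        time_s=step.contact_time_s,
        n_steps=n,
        target_m=state.target_m,
        left_avg_m=left_avg,
        right_avg_m=right_avg,
        score=score,
        hit=hit,
        refreshed=refresh,
        last_update_stride=last_update,
        display=display,
    )


def steps_from_events(
    events: list[FootContactEvent], speed: float
) -> list[StepRecord]:
    """Step records from a merged, time-ordered contact stream.

    The first contact has no predecessor and produces no estimate.
    """
    records: list[StepRecord] = []
    for i in range(1, len(events)):
        length = estimate_step_length(
            speed, events[i - 1].contact_time_s, events[i].contact_time_s
        )
        records.append(
            StepRecord(
                index=i,
                side=events[i].side,
                contact_time_s=events[i].contact_time_s,
                est_length_m=length,
            )
        )
    return records


def run_session(
    trial: GaitTrial,
    config: SessionConfig,
    *,
    fsr_threshold: float | None = None,
    min_phase_s: float = 0.100,
) -> tuple[list[StepRecord], list[BiofeedbackState]]:
    """Replay a trial through the real-time biofeedback loop.

    A causal pass over the trial's FSR streams: detect contacts, form
    Eq.-style step-length estimates from consecutive contact times, and
    update the interface state step by step.  Returns the step records
    and the full state timeline (one state per estimated step).
    """
    per_side = [
        detect_events_fsr(
            trial.t_fsr, trial.fsr[s], s, threshold=fsr_threshold,
            min_phase_s=min_phase_s,
        )
        for s in ("left", "right")
    ]
    events = merge_events(*per_side)
    steps = steps_from_events(events, config.walking_speed)
    if len(steps) < 4:
        raise ValueError(
            f"session invalid: only {len(steps)} estimated steps (need >= 4)"
        )

    state = BiofeedbackState(time_s=events[0].contact_time_s, n_steps=0,
                             target_m=config.target_m)
    timeline: list[BiofeedbackState] = []
    left_hist: list[float] = []
    right_hist: list[float] = []
    for step in steps:
        (left_hist if step.side == "left" else right_hist).append(step.est_length_m)
        state = step_feedback_update(state, config, step, left_hist, right_hist)
        timeline.append(state)
    return steps, timeline
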