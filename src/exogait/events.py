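"""Gait-phase detection: stance/swing finite-state machine over foot
sensors and force plates.

The real-time device path uses the force-sensitive-resistor (FSR)
voltage: a two-state (stance/swing) machine driven by threshold
crossings with a temporal debounce, which yields the foot-contact
times feeding the step-length estimator.  The offline reference path
uses the vertical ground reaction force with a 20 N threshold, the
standard motion-lab convention; validation compares the two.

Crossing times are refined by linear interpolation between the two
samples bracketing the threshold, so timing resolution is not limited
to the sampling period (both signals ramp linearly through their
thresholds).  The interpolation is causal: it uses only the current
and previous samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "FootContactEvent",
    "GaitEventError",
    "detect_events_fsr",
    "detect_events_force",
    "merge_events",
    "fsr_default_threshold",
]

DEFAULT_MIN_PHASE_S = 0.100
DEFAULT_FORCE_THRESHOLD_N = 20.0


class GaitEventError(ValueError):
    """Signal cannot support event detection (flat, chattering, or
    missing a swing phase)."""


@dataclass(frozen=True)
class FootContactEvent:
    """One detected stance phase: contact (heel strike) to toe-off."""

    side: str
    contact_time_s: float
    toe_off_time_s: float
    source: str = "fsr"  # fsr | force | truth

    def __post_init__(self) -> None:
        if not self.toe_off_time_s > self.contact_time_s:
            raise ValueError("toe_off_time_s must exceed contact_time_s")


def fsr_default_threshold(values: np.ndarray) -> float:
    """Midpoint of the 5th/95th percentile voltages of the trial."""
    lo, hi = np.percentile(values, [5.0, 95.0])
    return 0.5 * (lo + hi)


def _crossings(t: np.ndarray, x: np.ndarray, threshold: float):
    """Interpolated threshold-crossing times with directions (+1 up)."""
    above = x >= threshold
    change = np.flatnonzero(above[1:] != above[:-1])
    out_t = np.empty(len(change))
    out_d = np.empty(len(change), dtype=int)
    for j, i in enumerate(change):
        x0, x1 = x[i], x[i + 1]
        frac = (threshold - x0) / (x1 - x0)
        out_t[j] = t[i] + frac * (t[i + 1] - t[i])
        out_d[j] = 1 if above[i + 1] else -1
    return out_t, out_d


def _debounce(times: np.ndarray, dirs: np.ndarray, min_phase_s: float):
    """Cancel transition pairs bounding phases shorter than the window.

    A transition arriving sooner than ``min_phase_s`` after the previous
    accepted one cancels it (the short phase merges into its
    surroundings), which is how a latched state machine with a minimum
    dwell time behaves.
    """
    kept_t: list[float] = []
    kept_d: list[int] = []
    for tt, dd in zip(times, dirs):
        if kept_t and tt - kept_t[-1] < min_phase_s:
            kept_t.pop()
            kept_d.pop()
        else:
            kept_t.append(tt)
            kept_d.append(dd)
    return np.asarray(kept_t), np.asarray(kept_d, dtype=int)


def _pair_events(times, dirs, side, source):
    events: list[FootContactEvent] = []
    i = 0
    # drop a leading falling edge (trial begins mid-stance)
    while i < len(times) and dirs[i] == -1:
        i += 1
    while i + 1 < len(times):
        if dirs[i] == 1 and dirs[i + 1] == -1:
            events.append(
                FootContactEvent(side, float(times[i]), float(times[i + 1]), source)
            )
            i += 2
        else:  # pragma: no cover - alternation guaranteed by construction
            i += 1
    return events


def detect_events_fsr(
    t: np.ndarray,
    values: np.ndarray,
    side: str,
    threshold: float | None = None,
    min_phase_s: float = DEFAULT_MIN_PHASE_S,
) -> list[FootContactEvent]:
    """Stance/swing detection from an FSR voltage series.

    Contact is the upward threshold crossing, toe-off the downward one;
    phases shorter than ``min_phase_s`` (default 100 ms, the shortest
    plausible phase at the speeds of interest) are merged away.  The
    default threshold is the midpoint of the per-trial 5th/95th
    percentile voltages.  A flat signal yields an empty list with a
    warning.
    """
    t = np.asarray(t, dtype=float)
    values = np.asarray(values, dtype=float)
    if threshold is None:
        threshold = fsr_default_threshold(values)
    times, dirs = _crossings(t, values, threshold)
    if len(times) == 0:
        warnings.warn(
            f"FSR signal for side {side!r} never crosses threshold "
            f"{threshold:.3g}; no events detected",
            stacklevel=2,
        )
        return []
    times, dirs = _debounce(times, dirs, min_phase_s)
    return _pair_events(times, dirs, side, "fsr")


def detect_events_force(
    t: np.ndarray,
    grf: np.ndarray,
    side: str,
    newton_threshold: float = DEFAULT_FORCE_THRESHOLD_N,
    min_phase_s: float = 0.0,
) -> list[FootContactEvent]:
    """Heel-strike/toe-off from vertical GRF at a force threshold
    (default 20 N, the standard motion-lab convention).

    Rejects degenerate inputs: a side that never unloads (no swing
    phase) and chattering threshold crossings (median detected phase
    under 50 ms), which arise when the threshold sits inside the noise
    floor.
    """
    t = np.asarray(t, dtype=float)
    grf = np.asarray(grf, dtype=float)
    if np.all(grf > newton_threshold):
        raise GaitEventError(
            f"side {side!r}: load never falls below {newton_threshold} N "
            "(no swing phase)"
        )
    times, dirs = _crossings(t, grf, newton_threshold)
    if len(times) >= 4:
        median_phase = float(np.median(np.diff(times)))
        if median_phase < 0.050:
            raise GaitEventError(
                f"side {side!r}: threshold chatter ({len(times)} crossings, "
                f"median phase {median_phase * 1e3:.1f} ms); raise the "
                "threshold above the noise floor"
            )
    if min_phase_s > 0:
        times, dirs = _debounce(times, dirs, min_phase_s)
    return _pair_events(times, dirs, side, "force")


def merge_events(
    *event_lists: list[FootContactEvent], require_alternation: bool = False
) -> list[FootContactEvent]:
    """Merge per-side event lists into one contact-time-ordered stream."""
    merged = sorted(
        (e for lst in event_lists for e in lst), key=lambda e: e.contact_time_s
    )
    if require_alternation:
        for a, b in zip(merged, merged[1:]):
            if a.side == b.side:
                raise GaitEventError(
                    f"consecutive contacts on side {a.side!r} at "
                    f"{a.contact_time_s:.3f}/{b.contact_time_s:.3f} s"
                )
    return merged
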