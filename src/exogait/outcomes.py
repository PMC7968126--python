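"""Biomechanical outcomes: marker-based step length, joint kinetics,
support moment, stance-average positive power, per-limb averaging.

Conventions: extensor/plantarflexor moments positive; hip and knee
extension angles positive; ankle plantarflexion angle positive.  Joint
power is moment (Nm) times joint angular velocity (rad/s), the angular
velocity being the derivative of the 6 Hz low-pass-filtered joint
angle.  Stance-phase average positive power integrates the positive
part of the power curve over stance (trapezoidal rule with
interpolated window endpoints) and divides by stance time.  Kinetic
outcomes are normalized by body mass exactly once.  Outcomes are
computed per gait cycle over the 20 s analysis window, averaged within
each limb, then across limbs.

Stance windows come from the offline force-plate events (the
measurement reference), not the device's FSR path, and are half-open
``[contact, toe_off)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy import signal

from .assistance import decompose_biological, resample_torque
from .events import FootContactEvent, detect_events_force
from .synth import GaitTrial, JOINTS, SIDES

__all__ = [
    "OutcomeSummary",
    "step_length_from_markers",
    "support_moment",
    "angular_velocity",
    "avg_positive_power",
    "summarize_condition",
    "paired_step_series",
]

ANGVEL_LOWPASS_HZ = 6.0


@dataclass(frozen=True)
class OutcomeSummary:
    """Limb-and-cycle-averaged outcomes for one condition.

    Moments and powers are mass-normalized (Nm/kg, W/kg).  ``variant``
    distinguishes ``total`` (muscle + device at the ankle) from
    ``biological`` (device torque subtracted); they coincide for
    unpowered trials.
    """

    condition: str
    variant: str
    step_length_m: float
    peak_pf_angle_deg: float
    peak_knee_ext_deg: float
    peak_hip_ext_deg: float
    peak_ankle_moment_nmkg: float
    peak_knee_moment_nmkg: float
    peak_hip_moment_nmkg: float
    peak_support_moment_nmkg: float
    avg_pos_power_ankle_wkg: float
    avg_pos_power_knee_wkg: float
    avg_pos_power_hip_wkg: float
    avg_pos_power_exo_wkg: float
    avg_pos_power_summed_wkg: float
    n_cycles_left: int
    n_cycles_right: int
    limbs_averaged: bool = True

    def as_dict(self) -> dict:
        return asdict(self)


def step_length_from_markers(
    t_marker: np.ndarray,
    heel_left: np.ndarray,
    heel_right: np.ndarray,
    events: list[FootContactEvent],
) -> list[tuple[str, float, float]]:
    """Step length at each heel strike from heel-marker separation.

    Read out at the first marker frame at/after the contact: both heels
    are then in double support, moving with the belt, so their
    anterior-posterior separation is constant and equals the step
    length of the striking side.  Returns ``(side, contact_time_s,
    step_length_m)`` per usable event; events outside the marker record
    are skipped with a warning.
    """
    t_marker = np.asarray(t_marker, dtype=float)
    out: list[tuple[str, float, float]] = []
    for e in sorted(events, key=lambda ev: ev.contact_time_s):
        i = int(np.searchsorted(t_marker, e.contact_time_s))
        if i >= len(t_marker):
            warnings.warn(
                f"contact at {e.contact_time_s:.3f} s outside marker record; "
                "skipped",
                stacklevel=2,
            )
            continue
        sep = abs(float(heel_left[i]) - float(heel_right[i]))
        out.append((e.side, e.contact_time_s, sep))
    return out


def support_moment(
    ankle_nm: np.ndarray, knee_nm: np.ndarray, hip_nm: np.ndarray
) -> np.ndarray:
    """Whole-limb support moment: pointwise sum of the three extensor
    (plantarflexor) moments."""
    a = np.asarray(ankle_nm, dtype=float)
    k = np.asarray(knee_nm, dtype=float)
    h = np.asarray(hip_nm, dtype=float)
    if not (a.shape == k.shape == h.shape):
        raise ValueError("moment traces must have equal length")
    return a + k + h


def angular_velocity(
    angle_deg: np.ndarray, fs: float, lowpass_hz: float = ANGVEL_LOWPASS_HZ
) -> np.ndarray:
    """Joint angular velocity (rad/s) from an angle series (deg).

    The angle is low-pass filtered (4th-order zero-phase Butterworth,
    6 Hz default) before central differencing to suppress noise
    amplification by the derivative.
    """
    x = np.deg2rad(np.asarray(angle_deg, dtype=float))
    if lowpass_hz and lowpass_hz > 0:
        sos = signal.butter(4, lowpass_hz, btype="lowpass", fs=fs, output="sos")
        x = signal.sosfiltfilt(sos, x)
    return np.gradient(x, 1.0 / fs)


def _window_integrand(
    t: np.ndarray, y: np.ndarray, start: float, stop: float
) -> tuple[np.ndarray, np.ndarray]:
    """Clip a sampled curve to [start, stop] with interpolated endpoints."""
    i0 = int(np.searchsorted(t, start))
    i1 = int(np.searchsorted(t, stop))
    tt = np.concatenate(([start], t[i0:i1], [stop]))
    yy = np.concatenate(
        ([np.interp(start, t, y)], y[i0:i1], [np.interp(stop, t, y)])
    )
    return tt, yy


def avg_positive_power(
    t: np.ndarray,
    power_w: np.ndarray,
    stance_window: tuple[float, float],
) -> float:
    """Stance-average positive power: trapezoidal integral of
    ``max(P, 0)`` over the stance window divided by stance time."""
    start, stop = stance_window
    if not stop > start:
        raise ValueError(f"zero-length stance window [{start}, {stop}]")
    t = np.asarray(t, dtype=float)
    p = np.clip(np.asarray(power_w, dtype=float), 0.0, None)
    tt, pp = _window_integrand(t, p, start, stop)
    return float(np.trapezoid(pp, tt) / (stop - start))


def _peak_in_window(t, y, start, stop) -> float:
    i0 = int(np.searchsorted(t, start))
    i1 = int(np.searchsorted(t, stop))
    if i1 <= i0:
        return float("nan")
    return float(np.max(y[i0:i1]))


def summarize_condition(
    trial: GaitTrial,
    events: dict[str, list[FootContactEvent]] | None = None,
    window_s: tuple[float, float] | None = None,
    min_cycles: int = 3,
) -> dict[str, OutcomeSummary]:
    """Full outcome summary of one condition over its analysis window.

    Returns ``{"total": ..., "biological": ...}``; the two variants
    differ only at the ankle and only for powered trials.  Gait cycles
    are bounded by consecutive same-side force-plate contacts lying
    inside the window; a limb with fewer than ``min_cycles`` complete
    cycles rejects the trial.
    """
    if window_s is None:
        window_s = trial.analysis_window_s
    w0, w1 = window_s
    if events is None:
        events = {
            s: detect_events_force(trial.t_force, trial.grf[s], s)
            for s in SIDES
        }

    fs_marker = trial.config.rates["marker"]
    mass = trial.mass_kg
    t = trial.t_marker

    # device torque on the kinetics grid, per side
    exo_120 = {
        s: resample_torque(trial.t_fsr, trial.exo_torque[s], t) for s in SIDES
    }

    all_events = [e for s in SIDES for e in events[s]]
    marker_steps = step_length_from_markers(
        t, trial.heel["left"], trial.heel["right"], all_events
    )

    per_limb: dict[str, dict[str, list[dict[str, float]]]] = {
        s: {"total": [], "biological": []} for s in SIDES
    }
    n_cycles = {}
    for s in SIDES:
        own = [e for e in events[s] if w0 <= e.contact_time_s]
        cycles = [
            (own[i], own[i + 1])
            for i in range(len(own) - 1)
            if own[i + 1].contact_time_s <= w1
        ]
        n_cycles[s] = len(cycles)
        if len(cycles) < min_cycles:
            raise ValueError(
                f"limb {s!r}: only {len(cycles)} complete gait cycles in "
                f"window [{w0:.1f}, {w1:.1f}] s (need >= {min_cycles})"
            )

        ang = {j: trial.angles[(j, s)] for j in JOINTS}
        mom_total = {j: trial.moments[(j, s)] for j in JOINTS}
        mom_bio = dict(mom_total)
        mom_bio["ankle"] = decompose_biological(mom_total["ankle"], exo_120[s])
        omega = {j: angular_velocity(ang[j], fs_marker) for j in JOINTS}
        sup_total = support_moment(mom_total["ankle"], mom_total["knee"], mom_total["hip"])
        sup_bio = support_moment(mom_bio["ankle"], mom_bio["knee"], mom_bio["hip"])
        exo_power = exo_120[s] * omega["ankle"]

        side_lengths = [
            L for side_, tc, L in marker_steps
            if side_ == s and w0 <= tc <= w1
        ]

        for e_a, _e_b in cycles:
            stance = (e_a.contact_time_s, e_a.toe_off_time_s)
            for variant, mom, sup in (
                ("total", mom_total, sup_total),
                ("biological", mom_bio, sup_bio),
            ):
                powers = {
                    j: avg_positive_power(t, mom[j] * omega[j], stance)
                    for j in JOINTS
                }
                exo_pos = (
                    avg_positive_power(t, exo_power, stance)
                    if variant == "total"
                    else 0.0
                )
                per_limb[s][variant].append(
                    {
                        "peak_pf_angle_deg": _peak_in_window(t, ang["ankle"], *stance),
                        "peak_knee_ext_deg": _peak_in_window(t, ang["knee"], *stance),
                        "peak_hip_ext_deg": _peak_in_window(t, ang["hip"], *stance),
                        "peak_ankle_moment_nmkg": _peak_in_window(t, mom["ankle"], *stance) / mass,
                        "peak_knee_moment_nmkg": _peak_in_window(t, mom["knee"], *stance) / mass,
                        "peak_hip_moment_nmkg": _peak_in_window(t, mom["hip"], *stance) / mass,
                        "peak_support_moment_nmkg": _peak_in_window(t, sup, *stance) / mass,
                        "avg_pos_power_ankle_wkg": powers["ankle"] / mass,
                        "avg_pos_power_knee_wkg": powers["knee"] / mass,
                        "avg_pos_power_hip_wkg": powers["hip"] / mass,
                        "avg_pos_power_exo_wkg": exo_pos / mass,
                        "avg_pos_power_summed_wkg": (
                            powers["ankle"] + powers["knee"] + powers["hip"] + exo_pos
                        ) / mass,
                        "step_length_m": (
                            float(np.mean(side_lengths)) if side_lengths else float("nan")
                        ),
                    }
                )

    summaries = {}
    for variant in ("total", "biological"):
        limb_means = {
            s: {
                k: float(np.mean([c[k] for c in per_limb[s][variant]]))
                for k in per_limb[s][variant][0]
            }
            for s in SIDES
        }
        overall = {
            k: 0.5 * (limb_means["left"][k] + limb_means["right"][k])
            for k in limb_means["left"]
        }
        summaries[variant] = OutcomeSummary(
            condition=trial.condition,
            variant=variant,
            n_cycles_left=n_cycles["left"],
            n_cycles_right=n_cycles["right"],
            limbs_averaged=True,
            **overall,
        )
    return summaries


def paired_step_series(
    trial: GaitTrial,
    *,
    max_match_s: float = 0.15,
    window_s: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Device-estimated vs marker-measured step lengths, paired by event.

    The device side replays the trial's FSR streams through the
    real-time estimator; the measurement side takes heel-marker
    separations at force-plate heel strikes.  Each estimate is paired
    with the measured step whose contact time is nearest (within
    ``max_match_s``); unmatched steps are dropped.  Restrict to
    ``window_s`` to mimic a data-collection window.
    """
    from .feedback import steps_from_events  # deferred: no module cycle
    from .events import detect_events_fsr as _fsr, merge_events as _merge

    per_side = [
        _fsr(trial.t_fsr, trial.fsr[s], s) for s in SIDES
    ]
    est_steps = steps_from_events(_merge(*per_side), trial.walking_speed)

    force_events = [
        e for s in SIDES
        for e in detect_events_force(trial.t_force, trial.grf[s], s)
    ]
    measured = step_length_from_markers(
        trial.t_marker, trial.heel["left"], trial.heel["right"], force_events
    )
    # the first measured contact has no preceding step; drop it to match
    # the estimator convention
    measured = measured[1:]
    meas_t = np.array([tc for _, tc, _ in measured])
    meas_L = np.array([L for _, _, L in measured])

    est, meas = [], []
    for rec in est_steps:
        if window_s is not None and not (
            window_s[0] <= rec.contact_time_s <= window_s[1]
        ):
            continue
        if len(meas_t) == 0:
            break
        j = int(np.argmin(np.abs(meas_t - rec.contact_time_s)))
        if abs(meas_t[j] - rec.contact_time_s) <= max_match_s:
            est.append(rec.est_length_m)
            meas.append(meas_L[j])
    return np.asarray(est), np.asarray(meas)
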