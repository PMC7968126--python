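"""Synthetic multirate treadmill-gait generator with exact ground truth.

Emulates a laboratory treadmill session for an individual with crouch
gait: foot-sensor (FSR) voltages at 100 Hz, heel-marker trajectories at
120 Hz, vertical ground reaction forces at 980 Hz, raw surface EMG at
1926 Hz, joint angle/moment traces at the marker rate, and an
exoskeleton torque channel at 100 Hz, all sharing a common trigger at
``t = 0``.  Every trial stores its ground-truth foot-contact and
toe-off times and per-step lengths, so downstream estimators can be
validated against a known answer.

The treadmill identity is built in: with the belt at speed ``v``, the
true length of step *n* is ``v * (t_n - t_{n-1})`` where ``t_n`` are
successive (alternating-side) foot-contact times.  Heel trajectories
are constructed so that the left-right heel separation at each contact
equals that true step length exactly in the noiseless limit; during
stance the heel rides the belt backwards at ``-v``, and swing is a
quintic reconnection with belt-matched end velocity and zero end
acceleration.

Sensor imperfections are injected independently of the truth record:
contact-time jitter shifts the FSR pulse edges (emulating foot-sensor
/ state-machine latency), additive Gaussian noise corrupts the FSR
voltage and the heel markers, and EMG is band-limited noise amplitude
modulated by stance-phased activation envelopes over a configurable
noise floor.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import signal
from scipy.interpolate import BPoly

from .profiles import ParticipantProfile

__all__ = [
    "RATES",
    "GaitGenConfig",
    "GaitTrial",
    "generate_trial",
    "make_condition_set",
]

#: Stream sampling rates in Hz (foot sensors and exoskeleton log at
#: 100 Hz, motion capture at 120 Hz, force plates at 980 Hz, EMG at
#: 1926 Hz), synchronized by a trigger at t = 0.
RATES: dict[str, float] = {"fsr": 100.0, "marker": 120.0, "force": 980.0, "emg": 1926.0}

SIDES = ("left", "right")
JOINTS = ("ankle", "knee", "hip")
MUSCLES = ("soleus", "vastus")

# Gait-cycle geometry: stance occupies this fraction of the stride.
STANCE_FRACTION = 0.6
# FSR pulse: 30 ms linear rise centred on contact, 30 ms fall centred
# on toe-off (so the mid-amplitude crossing is an unbiased contact
# marker), riding between a swing baseline and a stance plateau.
FSR_RISE_S = 0.030
FSR_LOW_V = 0.1
FSR_HIGH_V = 3.0
# Vertical GRF ramps from zero over 5 ms after contact and back to zero
# over the last 5 ms of stance, so a 20 N threshold crossing stays
# within one 980 Hz sample of the true event for all cohort masses.
GRF_RISE_S = 0.005
_G = 9.81

_DEFAULT_STEP_TIME_S = 0.55  # per-side mean step time when no length is given


def _phase(t: np.ndarray, contacts: np.ndarray) -> np.ndarray:
    """Stride phase in [0, 1) for one side (0 = foot contact).

    Piecewise-linear between successive same-side contacts; clamped to
    the nearest cycle outside the recorded contacts.
    """
    idx = np.interp(t, contacts, np.arange(len(contacts), dtype=float))
    return np.mod(idx, 1.0)


def _gauss(x: np.ndarray, mu: float, sd: float) -> np.ndarray:
    return np.exp(-0.5 * ((x - mu) / sd) ** 2)


# --- per-cycle templates (phase in [0,1), stance = [0, STANCE_FRACTION)) ---

def _ankle_angle_deg(phi: np.ndarray) -> np.ndarray:
    """Ankle angle, plantarflexion positive: dorsiflexed midstance,
    plantarflexion peak at push-off, mild dorsiflexion in swing."""
    return (
        -10.0 * _gauss(phi, 0.30, 0.12)
        + 18.0 * _gauss(phi, 0.57, 0.05)
        - 5.0 * _gauss(phi, 0.78, 0.08)
    )


def _knee_angle_deg(phi: np.ndarray, crouch: float) -> np.ndarray:
    """Knee angle, extension positive; crouch shifts toward flexion."""
    return (
        -crouch
        - 12.0 * _gauss(phi, 0.08, 0.07)
        - 50.0 * _gauss(phi, 0.78, 0.09)
        + 8.0 * _gauss(phi, 0.45, 0.10)
    )


def _hip_angle_deg(phi: np.ndarray, crouch: float) -> np.ndarray:
    """Hip angle, extension positive; flexed at contact, most extended
    in late stance."""
    return -crouch + 12.0 - 15.0 * (1.0 + np.cos(2.0 * np.pi * (phi - 0.5)))


def _stance_u(phi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalized stance time u in [0,1] plus in-stance mask."""
    in_stance = phi < STANCE_FRACTION
    u = np.clip(phi / STANCE_FRACTION, 0.0, 1.0)
    return u, in_stance


def _moment_shape_ankle(u: np.ndarray) -> np.ndarray:
    # late-stance plantarflexor bump, exactly zero at stance edges
    return u**2 * np.sin(np.pi * u)


_ANKLE_SHAPE_MAX = float(np.max(_moment_shape_ankle(np.linspace(0, 1, 4001))))


def _ankle_moment_nmkg(phi: np.ndarray, peak: float) -> np.ndarray:
    u, st = _stance_u(phi)
    out = peak / _ANKLE_SHAPE_MAX * _moment_shape_ankle(u)
    out[~st] = 0.0
    return out


def _knee_moment_nmkg(phi: np.ndarray, peak: float) -> np.ndarray:
    u, st = _stance_u(phi)
    out = peak * np.sin(np.pi * u) ** 2
    out[~st] = 0.0
    return out


_HIP_SHAPE_MAX = float(
    np.max(np.sin(np.pi * np.linspace(0, 1, 4001)) * (1 - np.linspace(0, 1, 4001)))
)


def _hip_moment_nmkg(phi: np.ndarray, peak: float) -> np.ndarray:
    u, st = _stance_u(phi)
    out = peak / _HIP_SHAPE_MAX * np.sin(np.pi * u) * (1.0 - u)
    out[~st] = 0.0
    return out


def _emg_envelope(phi: np.ndarray, muscle: str, floor: float) -> np.ndarray:
    """Normalized activation envelope in [floor, 1]: soleus bursts in
    late stance, vastus lateralis in early stance (loading response)."""
    if muscle == "soleus":
        shape = _gauss(phi, 0.45, 0.07)
    elif muscle == "vastus":
        shape = _gauss(phi, 0.08, 0.05) + 0.25 * _gauss(phi, 0.97, 0.04)
    else:
        raise ValueError(f"unknown muscle {muscle!r}")
    shape = shape / shape.max() if shape.max() > 0 else shape
    return floor + (1.0 - floor) * shape


@dataclass(frozen=True)
class GaitGenConfig:
    """Configuration of one synthetic treadmill trial.

    ``mean_step_length_m`` is per side ``(left, right)``; the treadmill
    constraint fixes the per-side mean step *time* to
    ``mean_step_length_m / walking_speed``.  When omitted it defaults
    to a 0.55 s mean step time on both sides.

    Noise parameters are sensor-level only; the stored ground truth is
    never perturbed.  ``contact_jitter_sd_s`` shifts each FSR pulse
    edge (contact and toe-off independently), ``fsr_noise_sd`` is
    additive voltage noise, ``marker_noise_sd_m`` is additive heel
    marker noise (default 2 mm), ``emg_noise_floor`` is the resting
    fraction of the activation envelope.
    """

    profile: ParticipantProfile
    mean_step_length_m: tuple[float, float] | None = None
    step_time_cv: float = 0.04
    crouch_offset_deg: float = 15.0
    contact_jitter_sd_s: float = 0.0
    fsr_noise_sd: float = 0.02
    marker_noise_sd_m: float = 0.002
    emg_noise_floor: float = 0.10
    duration_s: float = 120.0
    seed: int = 0
    ankle_moment_peak_nmkg: float = 1.0
    hip_moment_peak_nmkg: float = 0.6
    rates: Mapping[str, float] = field(default_factory=lambda: dict(RATES))

    def __post_init__(self) -> None:
        v = self.profile.walking_speed
        if self.mean_step_length_m is None:
            L = v * _DEFAULT_STEP_TIME_S
            object.__setattr__(self, "mean_step_length_m", (L, L))
        else:
            msl = self.mean_step_length_m
            if np.isscalar(msl):
                msl = (float(msl), float(msl))  # type: ignore[arg-type]
            object.__setattr__(
                self, "mean_step_length_m", (float(msl[0]), float(msl[1]))
            )
        if any(L <= 0 for L in self.mean_step_length_m):
            raise ValueError("mean_step_length_m must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.step_time_cv < 0:
            raise ValueError("step_time_cv must be nonnegative")
        if any(r <= 0 for r in self.rates.values()):
            raise ValueError("all sampling rates must be positive")
        stride = sum(self.mean_step_time_s.values())
        if self.duration_s < 2.0 * stride:
            raise ValueError(
                f"duration_s={self.duration_s} shorter than two strides "
                f"({2 * stride:.2f} s)"
            )

    @property
    def mean_step_time_s(self) -> dict[str, float]:
        """Per-side mean step time implied by the treadmill constraint."""
        v = self.profile.walking_speed
        return {
            "left": self.mean_step_length_m[0] / v,
            "right": self.mean_step_length_m[1] / v,
        }

    def to_jsonable(self) -> dict:
        d = {
            "profile": vars(self.profile).copy(),
            "mean_step_length_m": list(self.mean_step_length_m),
            "step_time_cv": self.step_time_cv,
            "crouch_offset_deg": self.crouch_offset_deg,
            "contact_jitter_sd_s": self.contact_jitter_sd_s,
            "fsr_noise_sd": self.fsr_noise_sd,
            "marker_noise_sd_m": self.marker_noise_sd_m,
            "emg_noise_floor": self.emg_noise_floor,
            "duration_s": self.duration_s,
            "seed": self.seed,
            "ankle_moment_peak_nmkg": self.ankle_moment_peak_nmkg,
            "hip_moment_peak_nmkg": self.hip_moment_peak_nmkg,
            "rates": dict(self.rates),
        }
        return d

    @classmethod
    def from_jsonable(cls, d: dict) -> "GaitGenConfig":
        d = dict(d)
        d["profile"] = ParticipantProfile(**d["profile"])
        d["mean_step_length_m"] = tuple(d["mean_step_length_m"])
        return cls(**d)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_jsonable(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class GaitTrial:
    """One synthetic condition: multirate streams plus ground truth.

    ``truth`` columns: ``side``, ``contact_time_s``, ``toe_off_time_s``,
    ``true_step_length_m`` (NaN for the first contact, which has no
    predecessor).  All time vectors start at the shared trigger t=0.
    """

    config: GaitGenConfig
    condition: str
    t_fsr: np.ndarray
    fsr: dict[str, np.ndarray]
    t_marker: np.ndarray
    heel: dict[str, np.ndarray]
    angles: dict[tuple[str, str], np.ndarray]  # (joint, side) -> deg
    moments: dict[tuple[str, str], np.ndarray]  # (joint, side) -> Nm (total)
    t_force: np.ndarray
    grf: dict[str, np.ndarray]
    t_emg: np.ndarray
    emg: dict[tuple[str, str], np.ndarray]  # (muscle, side) -> mV
    emg_envelope: dict[tuple[str, str], np.ndarray]  # ground-truth envelope
    exo_torque: dict[str, np.ndarray]  # side -> Nm on t_fsr grid, PF positive
    truth: pd.DataFrame
    analysis_window_s: tuple[float, float]

    @property
    def walking_speed(self) -> float:
        return self.config.profile.walking_speed

    @property
    def mass_kg(self) -> float:
        return self.config.profile.mass_kg

    def truth_events(self, side: str | None = None) -> pd.DataFrame:
        if side is None:
            return self.truth
        return self.truth[self.truth["side"] == side].reset_index(drop=True)

    @property
    def powered(self) -> bool:
        return any(np.any(tau != 0) for tau in self.exo_torque.values())


def _contact_sequence(config: GaitGenConfig, rng: np.random.Generator):
    """Alternating L/R contact times, toe-offs, and true step lengths."""
    v = config.profile.walking_speed
    T = config.mean_step_time_s
    cv = config.step_time_cv

    times: list[float] = []
    sides: list[str] = []
    t = 0.45
    side_cycle = ("left", "right")
    k = 0
    while True:
        side = side_cycle[k % 2]
        if k == 0:
            tc = t
        else:
            dt = T[side] * (1.0 + cv * rng.standard_normal())
            dt = max(dt, 0.25 * T[side])
            tc = times[-1] + dt
        if tc > config.duration_s - 0.05:
            break
        times.append(tc)
        sides.append(side)
        k += 1
    times_a = np.asarray(times)
    if len(times_a) < 5:
        raise ValueError("duration shorter than two strides of usable gait")

    # toe-off at STANCE_FRACTION of each own stride
    toe_off = np.empty_like(times_a)
    for i in range(len(times_a)):
        if i + 2 < len(times_a):
            stride = times_a[i + 2] - times_a[i]
        else:
            stride = 2.0 * T[sides[i]]
        toe_off[i] = times_a[i] + STANCE_FRACTION * stride

    lengths = np.full(len(times_a), np.nan)
    lengths[1:] = v * np.diff(times_a)
    truth = pd.DataFrame(
        {
            "side": sides,
            "contact_time_s": times_a,
            "toe_off_time_s": toe_off,
            "true_step_length_m": lengths,
        }
    )
    return truth


def _heel_path(truth: pd.DataFrame, side: str, v: float) -> BPoly:
    """Anterior-posterior heel trajectory for one side.

    Stance segments are belt-speed lines; swing segments are the unique
    quintic with belt-matched velocity and zero acceleration at both
    ends.  Landing positions are solved so that the separation between
    the landing heel and the (stance) contralateral heel at each contact
    equals the true step length exactly.
    """
    land_x: dict[int, float] = {}
    last: dict[str, tuple[float, float]] = {}  # side -> (t_contact, x_land)
    for i, row in truth.iterrows():
        s = row["side"]
        other = "right" if s == "left" else "left"
        if i == 0:
            x = 0.0
        elif other not in last:
            # second contact before the other side has landed: anchor it
            x = float(row["true_step_length_m"])
        else:
            t_o, x_o = last[other]
            x_other_now = x_o - v * (row["contact_time_s"] - t_o)
            x = x_other_now + float(row["true_step_length_m"])
        land_x[i] = x
        last[s] = (float(row["contact_time_s"]), x)

    own = truth[truth["side"] == side]
    knots: list[float] = []
    derivs: list[list[float]] = []
    for i, row in own.iterrows():
        c = float(row["contact_time_s"])
        o = float(row["toe_off_time_s"])
        x = land_x[i]
        knots.extend([c, o])
        derivs.append([x, -v, 0.0])
        derivs.append([x - v * (o - c), -v, 0.0])
    return BPoly.from_derivatives(np.asarray(knots), derivs, extrapolate=True)


def _fsr_wave(
    t: np.ndarray,
    contacts: np.ndarray,
    toe_offs: np.ndarray,
    jitter_c: np.ndarray,
    jitter_o: np.ndarray,
) -> np.ndarray:
    """Trapezoidal FSR pulse train, rise/fall centred on the (jittered)
    contact and toe-off instants."""
    half = FSR_RISE_S / 2.0
    bp_t = [t[0] - 1.0]
    bp_v = [0.0]
    for c, o, jc, jo in zip(contacts, toe_offs, jitter_c, jitter_o):
        cj, oj = c + jc, o + jo
        bp_t.extend([cj - half, cj + half, oj - half, oj + half])
        bp_v.extend([0.0, 1.0, 1.0, 0.0])
    bp_t.append(t[-1] + 1.0)
    bp_v.append(0.0)
    bp_t_a = np.asarray(bp_t)
    if np.any(np.diff(bp_t_a) <= 0):
        # extreme jitter collapsed a phase; enforce monotonicity
        bp_t_a = np.maximum.accumulate(bp_t_a + 1e-9 * np.arange(len(bp_t_a)))
    w = np.interp(t, bp_t_a, np.asarray(bp_v))
    return FSR_LOW_V + (FSR_HIGH_V - FSR_LOW_V) * w


def _grf_wave(
    t: np.ndarray, contacts: np.ndarray, toe_offs: np.ndarray, mass: float
) -> np.ndarray:
    """Vertical GRF: body-weight trapezoid per stance with a double-bump
    modulation that is unity at the stance edges."""
    bw = mass * _G
    out = np.zeros_like(t)
    for c, o in zip(contacts, toe_offs):
        i0 = np.searchsorted(t, c)
        i1 = np.searchsorted(t, o, side="right")
        if i1 <= i0:
            continue
        tt = t[i0:i1]
        ramp = np.minimum(
            np.clip((tt - c) / GRF_RISE_S, 0.0, 1.0),
            np.clip((o - tt) / GRF_RISE_S, 0.0, 1.0),
        )
        u = (tt - c) / (o - c)
        shape = 1.0 + 0.2 * np.sin(np.pi * u) * np.sin(3.0 * np.pi * u)
        out[i0:i1] = bw * ramp * shape
    return out


def generate_trial(config: GaitGenConfig, condition: str = "baseline") -> GaitTrial:
    """Generate one synthetic treadmill trial.

    Deterministic for a fixed ``config.seed``.  The exoskeleton torque
    stream is identically zero; powered conditions are produced by
    :func:`make_condition_set`, which fits the assistance law to the
    trial's ankle moment.
    """
    rng = np.random.default_rng(config.seed)
    v = config.profile.walking_speed
    mass = config.profile.mass_kg

    truth = _contact_sequence(config, rng)
    contacts = {s: truth.loc[truth["side"] == s, "contact_time_s"].to_numpy() for s in SIDES}
    toe_offs = {s: truth.loc[truth["side"] == s, "toe_off_time_s"].to_numpy() for s in SIDES}

    n = {k: int(round(config.duration_s * r)) for k, r in config.rates.items()}
    t_fsr = np.arange(n["fsr"]) / config.rates["fsr"]
    t_marker = np.arange(n["marker"]) / config.rates["marker"]
    t_force = np.arange(n["force"]) / config.rates["force"]
    t_emg = np.arange(n["emg"]) / config.rates["emg"]

    # FSR with per-event timing jitter and voltage noise
    fsr = {}
    for s in SIDES:
        jc = config.contact_jitter_sd_s * np.clip(
            rng.standard_normal(len(contacts[s])), -3, 3
        )
        jo = config.contact_jitter_sd_s * np.clip(
            rng.standard_normal(len(toe_offs[s])), -3, 3
        )
        wave = _fsr_wave(t_fsr, contacts[s], toe_offs[s], jc, jo)
        if config.fsr_noise_sd > 0:
            wave = wave + config.fsr_noise_sd * rng.standard_normal(len(wave))
        fsr[s] = wave

    # Heel markers (noise added after exact geometric construction)
    heel = {}
    for s in SIDES:
        path = _heel_path(truth, s, v)
        x = path(t_marker)
        if config.marker_noise_sd_m > 0:
            x = x + config.marker_noise_sd_m * rng.standard_normal(len(x))
        heel[s] = x

    # Joint kinematics/kinetics on the marker grid
    angles = {}
    moments = {}
    knee_peak = 0.5 + 0.015 * config.crouch_offset_deg
    for s in SIDES:
        phi = _phase(t_marker, contacts[s])
        angles[("ankle", s)] = _ankle_angle_deg(phi)
        angles[("knee", s)] = _knee_angle_deg(phi, config.crouch_offset_deg)
        angles[("hip", s)] = _hip_angle_deg(phi, config.crouch_offset_deg)
        moments[("ankle", s)] = mass * _ankle_moment_nmkg(
            phi, config.ankle_moment_peak_nmkg
        )
        moments[("knee", s)] = mass * _knee_moment_nmkg(phi, knee_peak)
        moments[("hip", s)] = mass * _hip_moment_nmkg(
            phi, config.hip_moment_peak_nmkg
        )

    # Vertical GRF
    grf = {s: _grf_wave(t_force, contacts[s], toe_offs[s], mass) for s in SIDES}

    # EMG: band-limited carrier modulated by activation envelopes
    fs_emg = config.rates["emg"]
    sos = signal.butter(4, [20.0, 450.0], btype="bandpass", fs=fs_emg, output="sos")
    emg = {}
    emg_env = {}
    for s in SIDES:
        phi = _phase(t_emg, contacts[s])
        for m in MUSCLES:
            carrier = signal.sosfiltfilt(sos, rng.standard_normal(len(t_emg)))
            sd = carrier.std()
            if sd > 0:
                carrier = carrier / sd
            env = 0.5 * _emg_envelope(phi, m, config.emg_noise_floor)  # mV
            emg[(m, s)] = env * carrier
            emg_env[(m, s)] = env

    exo = {s: np.zeros_like(t_fsr) for s in SIDES}

    window = (max(0.0, config.duration_s - 20.0), config.duration_s)
    return GaitTrial(
        config=config,
        condition=condition,
        t_fsr=t_fsr,
        fsr=fsr,
        t_marker=t_marker,
        heel=heel,
        angles=angles,
        moments=moments,
        t_force=t_force,
        grf=grf,
        t_emg=t_emg,
        emg=emg,
        emg_envelope=emg_env,
        exo_torque=exo,
        truth=truth,
        analysis_window_s=window,
    )


def make_condition_set(
    profile: ParticipantProfile,
    seeds: Mapping[str, int] | tuple[int, int, int],
    *,
    duration_s: float = 120.0,
    bf_step_factor: float = 1.14,
    bf_crouch_reduction_deg: float = 4.0,
    assist_profile: "AssistanceProfile | None" = None,
    base_config: "GaitGenConfig | None" = None,
    **config_overrides,
) -> dict[str, GaitTrial]:
    """Three trials at the same fixed belt speed: ``baseline`` (shoes,
    no device torque), ``assist`` (adaptive plantarflexor + swing
    dorsiflexor torque), and ``bf_assist`` (assistance plus step-length
    biofeedback, emulated as longer steps and a modestly more extended
    posture).

    ``seeds`` maps condition name to generator seed (or is a 3-tuple in
    the order above).  Each trial lasts ``duration_s`` (default 120 s)
    with the final 20 s flagged as the analysis window.
    """
    from .assistance import AssistanceProfile, attach_assistance  # local: avoid cycle

    if not isinstance(seeds, Mapping):
        seeds = dict(zip(("baseline", "assist", "bf_assist"), seeds))
    if set(seeds) != {"baseline", "assist", "bf_assist"}:
        raise ValueError("seeds must cover baseline, assist, bf_assist")
    if base_config is not None:
        if base_config.profile.walking_speed != profile.walking_speed:
            raise ValueError("conditions must share the same walking speed")
        base_cfg = replace(base_config, seed=seeds["baseline"],
                           duration_s=duration_s)
    else:
        base_cfg = GaitGenConfig(
            profile=profile, duration_s=duration_s, seed=seeds["baseline"],
            **config_overrides,
        )
    trials = {"baseline": generate_trial(base_cfg, "baseline")}

    assist_cfg = replace(base_cfg, seed=seeds["assist"])
    trials["assist"] = generate_trial(assist_cfg, "assist")

    L = base_cfg.mean_step_length_m
    bf_cfg = replace(
        base_cfg,
        seed=seeds["bf_assist"],
        mean_step_length_m=(L[0] * bf_step_factor, L[1] * bf_step_factor),
        crouch_offset_deg=max(0.0, base_cfg.crouch_offset_deg - bf_crouch_reduction_deg),
    )
    trials["bf_assist"] = generate_trial(bf_cfg, "bf_assist")

    if assist_profile is None:
        assist_profile = AssistanceProfile(mass_kg=profile.mass_kg)
    if assist_profile.mass_kg != profile.mass_kg:
        raise ValueError("assistance profile mass must match the participant")
    for name in ("assist", "bf_assist"):
        attach_assistance(trials[name], assist_profile)
    return trials
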