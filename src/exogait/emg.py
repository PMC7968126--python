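"""Surface-EMG conditioning: linear envelope, normalization, stance iEMG.

The linear envelope is the standard chain: 4th-order zero-phase
Butterworth band-pass 15-380 Hz, full-wave rectification, 4th-order
zero-phase Butterworth low-pass at 7 Hz.  Envelopes are normalized by
the peak envelope from walking with the device unpowered (zero
torque).  Integrated EMG (iEMG) over the stance phase is the
trapezoidal integral of the normalized envelope divided by the stance
duration — a per-cycle muscle-work surrogate, averaged across cycles
and then limbs.
"""

from __future__ import annotations

import numpy as np
from scipy import signal

__all__ = [
    "linear_envelope",
    "normalize_envelope",
    "stance_iemg",
    "BANDPASS_HZ",
    "LOWPASS_HZ",
]

BANDPASS_HZ = (15.0, 380.0)
LOWPASS_HZ = 7.0
FILTER_ORDER = 4


def linear_envelope(raw_mv: np.ndarray, fs: float) -> np.ndarray:
    """EMG linear envelope: band-pass, rectify, low-pass (all
    zero-phase Butterworth).

    ``fs`` must exceed twice the band-pass upper cutoff.
    """
    if fs <= 2.0 * BANDPASS_HZ[1]:
        raise ValueError(
            f"sampling rate {fs} Hz too low for a {BANDPASS_HZ[1]} Hz "
            "band-pass edge (Nyquist violation)"
        )
    x = np.asarray(raw_mv, dtype=float)
    sos_bp = signal.butter(FILTER_ORDER, BANDPASS_HZ, btype="bandpass",
                           fs=fs, output="sos")
    sos_lp = signal.butter(FILTER_ORDER, LOWPASS_HZ, btype="lowpass",
                           fs=fs, output="sos")
    rectified = np.abs(signal.sosfiltfilt(sos_bp, x))
    env = signal.sosfiltfilt(sos_lp, rectified)
    # zero-phase low-pass can slightly undershoot; envelope is nonnegative
    return np.clip(env, 0.0, None)


def normalize_envelope(
    envelope: np.ndarray, reference_envelope: np.ndarray
) -> np.ndarray:
    """Scale an envelope by the peak of the zero-torque reference
    envelope (processed identically)."""
    ref_peak = float(np.max(reference_envelope, initial=0.0))
    if ref_peak <= 0:
        raise ValueError("reference envelope peak must be positive")
    return np.asarray(envelope, dtype=float) / ref_peak


def stance_iemg(
    t: np.ndarray,
    normalized_envelope: np.ndarray,
    stance_window: tuple[float, float],
) -> float:
    """Stance iEMG: trapezoidal integral of the envelope over the
    stance window divided by the stance duration (dimensionless)."""
    start, stop = stance_window
    if not stop > start:
        raise ValueError(f"empty stance window [{start}, {stop}]")
    t = np.asarray(t, dtype=float)
    y = np.asarray(normalized_envelope, dtype=float)
    i0 = int(np.searchsorted(t, start))
    i1 = int(np.searchsorted(t, stop))
    tt = np.concatenate(([start], t[i0:i1], [stop]))
    yy = np.concatenate(
        ([np.interp(start, t, y)], y[i0:i1], [np.interp(stop, t, y)])
    )
    return float(np.trapezoid(yy, tt) / (stop - start))
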