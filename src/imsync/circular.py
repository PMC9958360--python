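"""Circular statistics of dyadic movement phase.

The instantaneous phase of each (mean-centered) velocity series is taken
from its analytic signal (Hilbert construction).  Partner phase series are
compared with the Fisher–Lee circular correlation, and the continuous
relative phase ``dphi_t = wrap(phi_a - phi_b)`` is summarised by its
circular variance ``V = 1 - Rbar`` (low V = strong phase locking).

Phase of broadband, bursty velocity traces is intrinsically noisy; an
optional low-pass (Butterworth, default 2 Hz cutoff) can be applied before
the analytic signal, and is off by default.
"""

from __future__ import annotations

import numpy as np
from scipy import signal


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap angles to the interval (-pi, pi]."""
    phi = np.asarray(phi, dtype=float)
    return np.pi - np.mod(np.pi - phi, 2 * np.pi)


def instantaneous_phase(velocity: np.ndarray, frame_rate: float | None = None,
                        lowpass_hz: float | None = None) -> np.ndarray:
    """Instantaneous phase (radians, wrapped to (-pi, pi]) of a velocity
    series via the analytic signal of the mean-centered trace.

    ``lowpass_hz`` optionally band-limits the series first (requires
    ``frame_rate``).  A constant series has no defined phase and raises.
    """
    v = np.asarray(velocity, dtype=float)
    if v.ndim != 1:
        raise ValueError("expected a 1-D series")
    if np.ptp(v) == 0:
        raise ValueError("phase undefined for a constant series")
    x = v - v.mean()
    if lowpass_hz is not None:
        if frame_rate is None:
            raise ValueError("lowpass filtering requires frame_rate")
        sos = signal.butter(4, lowpass_hz, btype="low", fs=frame_rate, output="sos")
        x = signal.sosfiltfilt(sos, x)
        x = x - x.mean()
    return np.angle(signal.hilbert(x))


def circular_mean(phi: np.ndarray) -> float:
    """Direction of the mean resultant vector."""
    phi = np.asarray(phi, dtype=float)
    if phi.size == 0:
        raise ValueError("empty input")
    return float(np.angle(np.exp(1j * phi).mean()))


def circular_correlation(phi_a: np.ndarray, phi_b: np.ndarray) -> float:
    """Fisher–Lee circular correlation of two equal-length phase series:

    ``rho_c = sum sin(a - abar) sin(b - bbar) /
    sqrt(sum sin^2(a - abar) * sum sin^2(b - bbar))``

    with ``abar``, ``bbar`` the circular means.  Degenerate concentration
    (all deviations zero in either series) is signalled with a ValueError.
    """
    a = np.asarray(phi_a, dtype=float)
    b = np.asarray(phi_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("phase series must be 1-D and equal length")
    sa = np.sin(a - circular_mean(a))
    sb = np.sin(b - circular_mean(b))
    den = np.sqrt((sa ** 2).sum() * (sb ** 2).sum())
    if den == 0:
        raise ValueError("circular correlation undefined: degenerate concentration")
    return float((sa * sb).sum() / den)


def circular_variance(phi: np.ndarray) -> float:
    """Circular variance ``V = 1 - |mean resultant vector|``, in [0, 1]."""
    phi = np.asarray(phi, dtype=float)
    if phi.size == 0:
        raise ValueError("empty input")
    return float(1.0 - np.abs(np.exp(1j * phi).mean()))


def relative_phase(phi_a: np.ndarray, phi_b: np.ndarray) -> np.ndarray:
    """Continuous relative phase ``wrap(phi_a - phi_b)``."""
    a = np.asarray(phi_a, dtype=float)
    b = np.asarray(phi_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("phase series must have equal length")
    return wrap_phase(a - b)


def circular_variance_of_relative_phase(phi_a: np.ndarray,
                                        phi_b: np.ndarray) -> float:
    """Circular variance of the continuous relative phase of two series;
    low values indicate phase locking between the partners."""
    return circular_variance(relative_phase(phi_a, phi_b))
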