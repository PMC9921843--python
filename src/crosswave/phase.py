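"""Instantaneous phase and antagonist-muscle phase differences.

The instantaneous phase of a tremor envelope is the four-quadrant angle of its
analytic signal, Ψ(t) = angle(hilbert(x(t))).  Because phase is cyclic, the
difference of two phases is taken in the complex plane.  Two conventions are
provided and never silently substituted for each other:

* ``as_printed`` — angle(exp(iΨ1) − exp(iΨ2)), the *vector subtraction* rule.
  Note the difference of two unit vectors has a time-varying angle even when
  the true offset is constant (for Ψ2 = Ψ1 − φ the result is Ψ1 + (π + φ)/2,
  rotating with Ψ1).
* ``quotient`` — angle(exp(i(Ψ1 − Ψ2))), the conventional wrapped difference,
  which is constant for a constant offset and is what parameter-recovery
  tests use.

Averaging likewise comes in an ``arithmetic`` flavour (plain mean of the
wrapped angles, discontinuous at ±π, which matters for alternating tremor)
and a ``circular`` flavour (angle of the mean unit vector).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .preprocess import TremorPair, bandpass_zero_phase

__all__ = [
    "PhaseSeries",
    "FrequencyRange",
    "instantaneous_phase",
    "phase_difference",
    "mean_phase_difference",
    "band_mean_phase_difference",
    "wrap_phase",
]

#: Fraction of samples excluded at each end before averaging (filter and
#: Hilbert edge effects are concentrated there).
DEFAULT_EDGE_FRACTION = 0.05


@dataclass
class PhaseSeries:
    """Per-sample phase in radians, wrapped to [-pi, pi]."""

    values: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.abs(self.values) > np.pi + 1e-12):
            raise ValueError("phase values must lie in [-pi, pi]")

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class FrequencyRange:
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 < self.lo < self.hi:
            raise ValueError(f"invalid frequency range ({self.lo}, {self.hi})")


def wrap_phase(x: np.ndarray) -> np.ndarray:
    """Wrap angles to [-pi, pi]."""
    return np.angle(np.exp(1j * np.asarray(x, dtype=float)))


def instantaneous_phase(x: np.ndarray, fs: float) -> PhaseSeries:
    """Phase of the analytic signal, per sample.

    An all-zero (degenerate) signal has no defined phase; the angle-of-zero
    convention (0) is returned with a warning.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite samples")
    if len(x) < 2:
        raise ValueError("series must have length >= 2")
    if not np.any(x):
        warnings.warn("degenerate all-zero signal: phase reported as 0", RuntimeWarning)
        return PhaseSeries(np.zeros_like(x), fs)
    return PhaseSeries(np.angle(sps.hilbert(x)), fs)


def phase_difference(p1: PhaseSeries, p2: PhaseSeries, mode: str = "as_printed") -> PhaseSeries:
    """Per-sample cyclic difference of two phase series (see module docs)."""
    if len(p1) != len(p2) or p1.fs != p2.fs:
        raise ValueError("phase series must have equal length and sampling rate")
    z1 = np.exp(1j * p1.values)
    z2 = np.exp(1j * p2.values)
    if mode == "as_printed":
        z = z1 - z2
        degenerate = np.abs(z) < 1e-12
        if np.any(degenerate):
            warnings.warn(
                "identical phases at some samples: vector difference is the "
                "zero vector, angle reported as 0",
                RuntimeWarning,
            )
        return PhaseSeries(np.where(degenerate, 0.0, np.angle(z)), p1.fs)
    if mode == "quotient":
        return PhaseSeries(np.angle(z1 * np.conj(z2)), p1.fs)
    raise ValueError(f"unknown mode {mode!r}")


def mean_phase_difference(d: PhaseSeries | np.ndarray, averaging: str = "arithmetic") -> float:
    """Average a phase-difference series to one scalar per subject.

    arithmetic : plain mean of the wrapped angles (the printed definition).
    circular   : angle of the mean unit vector; an exact antipodal tie
                 (mean vector of zero length) deterministically returns +pi.
    """
    values = d.values if isinstance(d, PhaseSeries) else np.asarray(d, dtype=float)
    if values.size == 0:
        raise ValueError("cannot average an empty phase series")
    if averaging == "arithmetic":
        return float(np.mean(values))
    if averaging == "circular":
        z = np.mean(np.exp(1j * values))
        if abs(z) < 1e-12:
            return float(np.pi)
        ang = float(np.angle(z))
        return float(np.pi) if ang <= -np.pi else ang
    raise ValueError(f"unknown averaging {averaging!r}")


def band_mean_phase_difference(
    pair: TremorPair,
    band: FrequencyRange,
    order: int = 8,
    mode: str = "as_printed",
    averaging: str = "arithmetic",
    edge_fraction: float = DEFAULT_EDGE_FRACTION,
) -> float:
    """Mean flexor-minus-extensor phase difference inside a frequency band.

    Composition: zero-phase band-pass of both envelopes → instantaneous phase
    of each → cyclic difference → average, excluding ``edge_fraction`` of the
    samples at each end.
    """
    if not band.hi < pair.fs / 2:
        raise ValueError(f"band upper bound {band.hi} Hz reaches Nyquist ({pair.fs / 2} Hz)")
    fx = bandpass_zero_phase(pair.flexor_env, pair.fs, band.lo, band.hi, order)
    ex = bandpass_zero_phase(pair.extensor_env, pair.fs, band.lo, band.hi, order)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        d = phase_difference(
            instantaneous_phase(fx, pair.fs), instantaneous_phase(ex, pair.fs), mode
        )
    n = len(d)
    k = int(np.floor(edge_fraction * n))
    interior = d.values[k : n - k] if n - 2 * k >= 1 else d.values
    return mean_phase_difference(PhaseSeries(interior, pair.fs), averaging)
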