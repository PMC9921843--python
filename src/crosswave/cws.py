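"""Complex-Morlet continuous wavelet transform and cross-wavelet spectra.

The analyzing wavelet is the complex Morlet

    M(t) = (1/sqrt(pi*Fb)) * exp(2*pi*i*Fc*t) * exp(-t^2/Fb),

with bandwidth coefficient Fb and central-frequency coefficient Fc (defaults
Fb = 1, Fc = 1).  Scales map to pseudo-frequencies by the standard Morlet
convention f = Fc / (s * dt).  The transform is evaluated per scale as an FFT
multiplication with the wavelet's analytic frequency response

    H(f) = exp(-pi^2 * Fb * Fc^2 * (f/f_center - 1)^2),

which is the L1-normalized convention: a cosine of amplitude A produces a
ridge magnitude of A/2 at every analysis frequency, so power is comparable
across scales.

The cross-wavelet spectrum of a channel pair is Wxy = Wx * conj(Wy) with
x = flexor, y = extensor: |Wxy| measures simultaneously elevated power in both
channels, angle(Wxy) the inter-channel phase shift.  Sign convention (fixed
package-wide): positive phase ⟺ the flexor leads the extensor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft

from .preprocess import TremorPair

__all__ = [
    "MorletParams",
    "CrossWaveletSpectrum",
    "morlet_wavelet",
    "cwt",
    "cross_wavelet_spectrum",
    "frequency_grid",
]

_SCALE_CHUNK = 64  # scales per FFT block, caps transform memory


@dataclass(frozen=True)
class MorletParams:
    """Complex Morlet wavelet parameters (bandwidth Fb, central frequency Fc)."""

    Fb: float = 1.0
    Fc: float = 1.0

    def __post_init__(self) -> None:
        if not (self.Fb > 0 and self.Fc > 0):
            raise ValueError("Fb and Fc must be positive")


def morlet_wavelet(t, params: MorletParams = MorletParams()):
    """The complex Morlet wavelet M(t) evaluated at time(s) t."""
    t = np.asarray(t, dtype=float)
    out = (
        1.0 / np.sqrt(np.pi * params.Fb)
        * np.exp(2j * np.pi * params.Fc * t)
        * np.exp(-(t ** 2) / params.Fb)
    )
    return complex(out) if out.ndim == 0 else out


def frequency_grid(lo: float = 0.5, hi: float = 60.0, step: float = 0.1) -> np.ndarray:
    """Ascending analysis-frequency grid [lo, hi] with the given step."""
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


def _validate_freqs(freqs: np.ndarray, fs: float) -> np.ndarray:
    freqs = np.asarray(freqs, dtype=float)
    if freqs.ndim != 1 or freqs.size == 0:
        raise ValueError("freqs must be a non-empty 1-D grid")
    if np.any(np.diff(freqs) <= 0):
        raise ValueError("freqs must be strictly increasing")
    if freqs[0] <= 0 or freqs[-1] >= fs / 2:
        raise ValueError(f"freqs must lie inside (0, {fs / 2}) Hz")
    return freqs


def cwt(
    x: np.ndarray, fs: float, freqs: np.ndarray, params: MorletParams = MorletParams()
) -> np.ndarray:
    """Continuous wavelet transform on an analysis-frequency grid.

    Returns a complex (len(freqs), len(x)) matrix with rows ordered as
    ``freqs``.  The series must cover at least two periods of the lowest
    analysis frequency.
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite samples")
    freqs = _validate_freqs(freqs, fs)
    n = x.size
    if n / fs < 2.0 / freqs[0]:
        raise ValueError(
            f"series of {n / fs:.3g} s covers fewer than 2 periods of {freqs[0]} Hz"
        )
    # zero-pad past the widest wavelet's support to kill circular wrap-around
    smax_samples = params.Fc * fs / freqs[0]
    pad = int(np.ceil(5.0 * np.sqrt(params.Fb) * smax_samples)) + 1
    nfft = sfft.next_fast_len(n + pad)
    X = sfft.fft(x, nfft)
    f_dft = sfft.fftfreq(nfft, d=1.0 / fs)
    out = np.empty((freqs.size, n), dtype=complex)
    for start in range(0, freqs.size, _SCALE_CHUNK):
        fc_block = freqs[start : start + _SCALE_CHUNK, None]
        expo = -np.pi ** 2 * params.Fb * params.Fc ** 2 * (f_dft[None, :] / fc_block - 1.0) ** 2
        H = np.exp(np.maximum(expo, -745.0))  # underflow guard
        out[start : start + _SCALE_CHUNK] = sfft.ifft(X[None, :] * H, axis=1)[:, :n]
    return out


@dataclass
class CrossWaveletSpectrum:
    """Complex cross-wavelet spectrum of a flexor/extensor pair.

    ``W[k, n]`` corresponds to frequency ``freqs[k]`` and time ``times[n]``.
    """

    times: np.ndarray
    freqs: np.ndarray
    W: np.ndarray
    fs: float
    params: MorletParams = field(default_factory=MorletParams)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.freqs = np.asarray(self.freqs, dtype=float)
        if self.W.shape != (self.freqs.size, self.times.size):
            raise ValueError("W must have shape (len(freqs), len(times))")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")
        if not np.all(np.isfinite(self.W)):
            raise ValueError("spectrum contains non-finite values")

    @property
    def power(self) -> np.ndarray:
        """|Wxy|: co-occurring spectral power of the two channels (cached)."""
        cached = getattr(self, "_power", None)
        if cached is None or cached.shape != self.W.shape:
            cached = np.abs(self.W)
            object.__setattr__(self, "_power", cached)
        return cached

    @property
    def phase(self) -> np.ndarray:
        """angle(Wxy) in [-pi, pi]: per-cell inter-channel phase shift."""
        return np.angle(self.W)

    @property
    def duration_s(self) -> float:
        return self.times.size / self.fs

    def coi_mask(self, multiplier: float = 1.0) -> np.ndarray:
        """Boolean (freq x time) mask, True where a cell lies within one
        e-folding width of the wavelet envelope from either record edge
        (boundary-corrupted region)."""
        width = multiplier * np.sqrt(self.params.Fb) * self.params.Fc * self.fs / self.freqs
        idx = np.arange(self.times.size)
        lead = idx[None, :] < width[:, None]
        trail = (self.times.size - 1 - idx)[None, :] < width[:, None]
        return lead | trail


def cross_wavelet_spectrum(
    pair: TremorPair, freqs: np.ndarray, params: MorletParams = MorletParams()
) -> CrossWaveletSpectrum:
    """Cross-wavelet spectrum Wx * conj(Wy) of the flexor (x) and extensor (y)
    envelopes of a tremor pair."""
    wx = cwt(pair.flexor_env, pair.fs, freqs, params)
    wy = cwt(pair.extensor_env, pair.fs, freqs, params)
    n = len(pair)
    # explicit real arithmetic keeps the Hermitian swap property bit-exact
    # (channel swap conjugates the spectrum with no rounding asymmetry)
    re = wx.real * wy.real + wx.imag * wy.imag
    im = wx.imag * wy.real - wx.real * wy.imag
    return CrossWaveletSpectrum(
        times=np.arange(n) / pair.fs,
        freqs=np.asarray(freqs, dtype=float),
        W=re + 1j * im,
        fs=pair.fs,
        params=params,
    )
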