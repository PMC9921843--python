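import numpy as np
import pytest

from crosswave.preprocess import TremorPair


def sinusoid_pair(
    freq: float = 5.0,
    offset: float = 0.0,
    fs: float = 125.0,
    duration_s: float = 60.0,
    amplitude: float = 0.5,
    baseline: float = 1.0,
    subject_id: str = "anon",
) -> TremorPair:
    """Envelope pair carrying one sustained oscillation; the flexor-minus-
    extensor phase equals ``offset``."""
    t = np.arange(int(duration_s * fs)) / fs
    return TremorPair(
        flexor_env=baseline + amplitude * np.cos(2 * np.pi * freq * t),
        extensor_env=baseline + amplitude * np.cos(2 * np.pi * freq * t - offset),
        fs=fs,
        subject_id=subject_id,
    )


def burst_pair(
    freq: float = 5.0,
    offset: float = 0.0,
    onsets=(15.0,),
    burst_duration_s: float = 2.0,
    amplitude: float = 10.0,
    fs: float = 125.0,
    duration_s: float = 30.0,
    window: str = "hann",
) -> TremorPair:
    """Envelope pair with deterministic bursts at the given onsets."""
    n = int(duration_s * fs)
    t = np.arange(n) / fs
    fx = np.zeros(n)
    ex = np.zeros(n)
    for t0 in onsets:
        i0 = int(round(t0 * fs))
        i1 = min(n, i0 + int(round(burst_duration_s * fs)))
        seg = t[i0:i1]
        if window == "hann":
            win = 0.5 * (1 - np.cos(2 * np.pi * (seg - seg[0]) / (seg[-1] - seg[0])))
        else:  # gaussian
            center = 0.5 * (seg[0] + seg[-1])
            sigma = burst_duration_s / 6.0
            win = np.exp(-0.5 * ((seg - center) / sigma) ** 2)
        carrier = 2 * np.pi * freq * (seg - seg[0])
        fx[i0:i1] += amplitude * win * 0.5 * (1 + np.cos(carrier))
        ex[i0:i1] += amplitude * win * 0.5 * (1 + np.cos(carrier - offset))
    return TremorPair(flexor_env=fx, extensor_env=ex, fs=fs)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
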