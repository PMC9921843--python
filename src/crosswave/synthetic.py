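"""Seeded synthetic tremor recordings and cohorts with planted structure.

Clinical antagonist-muscle recordings are not distributable, so every other
module is exercised against synthetic signals whose ground truth is known.
The generator emulates the structure visible in real tremor envelopes:

* envelope mode (default): a non-negative pair of tremor envelopes — folded
  Gaussian baseline noise plus band-limited oscillatory bursts.  Burst onsets
  form a Poisson process (with non-overlap rejection), each burst is a
  raised-cosine (Hann) window of the configured mean duration modulating a
  sinusoid at the component's central frequency.  The extensor's oscillation
  is shifted so that the flexor-minus-extensor phase equals ``phase_offset``
  (≈0 plants a synchronous pattern, ≈±π an alternating one).
* raw-EMG mode: a broadband 60-240 Hz carrier amplitude-modulated by the
  envelope-mode tremor waveform, plus 50 Hz line interference and white
  noise, so the full preprocessing chain is exercised end to end.

Recordings default to 90 s, the clinical protocol length.  All randomness
flows from integer seeds through ``numpy.random.default_rng``; identical
seeds give identical data on every platform.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io_emg import Recording
from .preprocess import TremorPair

__all__ = [
    "TremorSpec",
    "CohortSpec",
    "simulate_tremor_pair",
    "simulate_raw_emg",
    "simulate_cohorts",
    "preset_cohort_spec",
    "PRESETS",
]


@dataclass(frozen=True)
class TremorSpec:
    """One oscillatory tremor component of a synthetic subject.

    phase_offset is the flexor-minus-extensor phase of the burst oscillation
    (positive ⟺ flexor leads), matching the package-wide sign convention.
    freq_jitter_Hz draws each subject's central frequency uniformly within
    ±freq_jitter_Hz of burst_freq (0 = fixed frequency).
    """

    burst_freq: float = 5.0
    burst_rate: float = 0.3
    burst_duration_s: float = 1.0
    burst_amplitude: float = 10.0
    phase_offset: float = 0.0
    amplitude_jitter: float = 0.2
    noise_sd: float = 1.0
    duration_s: float = 90.0
    fs: float = 125.0
    freq_jitter_Hz: float = 0.0

    def __post_init__(self) -> None:
        if min(self.burst_rate, self.burst_duration_s, self.burst_amplitude, self.noise_sd) < 0:
            raise ValueError("rates, durations, amplitudes and noise sd must be >= 0")
        if not self.duration_s > 0:
            raise ValueError("duration_s must be positive")
        if not self.fs > 2 * self.burst_freq:
            raise ValueError(
                f"fs = {self.fs} Hz cannot represent bursts at {self.burst_freq} Hz"
            )


@dataclass(frozen=True)
class CohortSpec:
    """A cohort of synthetic subjects sharing component specs and a seed.

    Each subject receives every component in ``components`` (real Parkinsonian
    tremor shows simultaneous alternating ~4-6 Hz and synchronous ~8-18 Hz
    components, so multiple bands may coexist).
    """

    n_subjects: int
    components: tuple
    group: str = "other"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not self.components:
            raise ValueError("at least one TremorSpec component required")


def _burst_onsets(rng: np.random.Generator, spec: TremorSpec) -> np.ndarray:
    """Poisson burst onsets with rejection of overlaps within the component."""
    n_expected = rng.poisson(spec.burst_rate * spec.duration_s)
    if n_expected == 0 or spec.burst_duration_s == 0:
        return np.empty(0)
    latest = spec.duration_s - spec.burst_duration_s
    if latest <= 0:
        return np.empty(0)
    onsets: list[float] = []
    candidates = np.sort(rng.uniform(0.0, latest, size=n_expected))
    for t0 in candidates:
        if not onsets or t0 - onsets[-1] >= spec.burst_duration_s:
            onsets.append(float(t0))
    return np.asarray(onsets)


def _component_waveforms(
    rng: np.random.Generator, spec: TremorSpec, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Flexor and extensor waveforms of one burst component (non-negative)."""
    t = np.arange(n) / spec.fs
    fx = np.zeros(n)
    ex = np.zeros(n)
    freq = spec.burst_freq
    if spec.freq_jitter_Hz > 0:
        freq = float(rng.uniform(spec.burst_freq - spec.freq_jitter_Hz,
                                 spec.burst_freq + spec.freq_jitter_Hz))
    for t0 in _burst_onsets(rng, spec):
        amp = spec.burst_amplitude
        if spec.amplitude_jitter > 0:
            amp = max(0.0, amp * (1.0 + spec.amplitude_jitter * rng.standard_normal()))
        i0 = int(round(t0 * spec.fs))
        i1 = min(n, i0 + int(round(spec.burst_duration_s * spec.fs)))
        if i1 - i0 < 2:
            continue
        seg = t[i0:i1]
        window = 0.5 * (1.0 - np.cos(2 * np.pi * (seg - seg[0]) / (seg[-1] - seg[0])))
        carrier = 2 * np.pi * freq * (seg - seg[0])
        # oscillation kept non-negative: (1 + cos)/2 modulated by the window
        fx[i0:i1] += amp * window * 0.5 * (1.0 + np.cos(carrier))
        ex[i0:i1] += amp * window * 0.5 * (1.0 + np.cos(carrier - spec.phase_offset))
    return fx, ex


def simulate_tremor_pair(
    spec: TremorSpec | list | tuple,
    seed: int,
    subject_id: str = "synthetic",
    group: str = "other",
    side: str = "left",
    age: float | None = None,
) -> TremorPair:
    """Simulate an envelope-domain tremor pair (one or several components)."""
    specs = list(spec) if isinstance(spec, (list, tuple)) else [spec]
    if not specs:
        raise ValueError("at least one TremorSpec required")
    fs = specs[0].fs
    dur = specs[0].duration_s
    for s in specs:
        if s.fs != fs or s.duration_s != dur:
            raise ValueError("all components must share fs and duration_s")
    rng = np.random.default_rng(seed)
    n = int(round(dur * fs))
    noise_sd = specs[0].noise_sd
    fx = np.abs(rng.standard_normal(n)) * noise_sd
    ex = np.abs(rng.standard_normal(n)) * noise_sd
    for s in specs:
        cf, ce = _component_waveforms(rng, s, n)
        fx += cf
        ex += ce
    return TremorPair(
        flexor_env=fx, extensor_env=ex, fs=fs,
        subject_id=subject_id, group=group, side=side, age=age,
    )


def simulate_raw_emg(
    spec: TremorSpec,
    seed: int,
    subject_id: str = "synthetic",
    group: str = "other",
    side: str = "left",
    line_amplitude: float = 5.0,
    carrier_band: tuple = (60.0, 240.0),
) -> Recording:
    """Simulate a raw 500 Hz surface-EMG recording.

    The tremor waveform (envelope mode at the raw rate) amplitude-modulates a
    band-limited 60-240 Hz noise carrier per channel; 50 Hz line interference
    and a small white-noise floor are added on top.
    """
    from scipy import signal as sps

    if spec.fs != 500.0:
        raise ValueError("raw-EMG mode requires fs = 500 Hz")
    rng = np.random.default_rng(seed)
    pair = simulate_tremor_pair(spec, seed=int(rng.integers(2 ** 31)), subject_id=subject_id)
    n = len(pair)
    t = np.arange(n) / spec.fs
    sos = sps.butter(4, carrier_band, btype="bandpass", fs=spec.fs, output="sos")

    def channel(env: np.ndarray) -> np.ndarray:
        carrier = sps.sosfiltfilt(sos, rng.standard_normal(n))
        carrier /= max(np.std(carrier), 1e-12)
        line = line_amplitude * np.sin(2 * np.pi * 50.0 * t)
        return carrier * env + line + 0.1 * spec.noise_sd * rng.standard_normal(n)

    return Recording(
        flexor=channel(pair.flexor_env),
        extensor=channel(pair.extensor_env),
        fs=spec.fs,
        subject_id=subject_id,
        group=group,
        side=side,
    )


# ---------------------------------------------------------------------------
# cohort presets
#
# pd_like plants the two simultaneous Parkinsonian components (an alternating
# 4-6 Hz component and a weaker synchronous 8-18 Hz one); et_like plants the
# essential-tremor bands (2.2-3.9 Hz and 10-37 Hz, phase unconstrained).
# Rates/amplitudes/durations are fixed realistic defaults: ~0.3-0.4 bursts/s,
# ~1 s bursts, burst SNR ~10 against a 1 uV folded-normal floor.

PRESETS: dict = {}


def _make_presets() -> None:
    pd_a = TremorSpec(
        burst_freq=5.0, freq_jitter_Hz=0.8, burst_rate=0.5, burst_duration_s=1.0,
        burst_amplitude=20.0, phase_offset=np.pi, amplitude_jitter=0.2, noise_sd=1.0,
    )
    pd_b = TremorSpec(
        burst_freq=13.0, freq_jitter_Hz=4.0, burst_rate=0.3, burst_duration_s=0.6,
        burst_amplitude=10.0, phase_offset=0.0, amplitude_jitter=0.2, noise_sd=1.0,
    )
    et_a = TremorSpec(
        burst_freq=3.0, freq_jitter_Hz=0.7, burst_rate=0.35, burst_duration_s=1.2,
        burst_amplitude=8.0, phase_offset=0.5, amplitude_jitter=0.2, noise_sd=1.0,
    )
    et_b = TremorSpec(
        burst_freq=20.0, freq_jitter_Hz=8.0, burst_rate=0.35, burst_duration_s=0.5,
        burst_amplitude=5.0, phase_offset=-1.0, amplitude_jitter=0.2, noise_sd=1.0,
    )
    PRESETS["pd_like"] = (pd_a, pd_b)
    PRESETS["et_like"] = (et_a, et_b)


_make_presets()


def preset_cohort_spec(name: str, n_subjects: int = 10, seed: int = 0) -> CohortSpec:
    """CohortSpec for a named preset ('pd_like' or 'et_like')."""
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    group = "PD" if name == "pd_like" else ("ET" if name == "et_like" else "other")
    return CohortSpec(n_subjects=n_subjects, components=PRESETS[name], group=group, seed=seed)


def _simulate_cohort(spec: CohortSpec) -> list[TremorPair]:
    rng = np.random.default_rng(spec.seed)
    pairs = []
    for k in range(spec.n_subjects):
        subject_seed = int(rng.integers(2 ** 31))
        comps = []
        for comp in spec.components:
            if comp.phase_offset in (np.pi, -np.pi):
                # alternating components: draw the sign of the +-pi offset
                comp = replace(comp, phase_offset=float(np.pi) * (1 if rng.random() < 0.5 else -1))
            comps.append(comp)
        pairs.append(
            simulate_tremor_pair(
                comps, seed=subject_seed,
                subject_id=f"{spec.group.lower()}{k:02d}", group=spec.group,
            )
        )
    return pairs


def simulate_cohorts(pos: CohortSpec, neg: CohortSpec) -> tuple[list[TremorPair], list[TremorPair]]:
    """Simulate two cohorts; per-subject seeds derive from each cohort seed."""
    return _simulate_cohort(pos), _simulate_cohort(neg)
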