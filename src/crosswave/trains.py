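"""Cross-wave train detection and characterization.

A *cross-wave train* is a time- and frequency-localized increase of
cross-wavelet power: a strict local maximum of |Wxy| over its 8-neighborhood
in the (frequency x time) matrix.  Each retained maximum is characterized by

* central (leading) frequency and peak time,
* peak PSD (|Wxy| at the peak, in this implementation's L1-normalized
  cross-wavelet power units — not calibrated against any external unit),
* duration: contiguous half-power extent (|W| >= peak/2) along the time axis
  at the peak's frequency row, in seconds and in periods
  (duration_s x central frequency),
* bandwidth: contiguous half-power extent along the frequency axis at the
  peak's time column, in Hz,
* instantaneous phase: angle(Wxy) at the peak.

Detection is threshold-free apart from a relative floor discarding
numerical-noise maxima; maxima inside the cone of influence are excluded by
default, and overlapping maxima (each inside the other's half-power
time x frequency box) are deduplicated keeping the stronger one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage

from .cws import CrossWaveletSpectrum
from .io_emg import TRAIN_COLUMNS

__all__ = [
    "CrossWaveTrain",
    "TrainFilter",
    "DetectionConfig",
    "detect_cross_wave_trains",
    "measure_train",
    "filter_trains",
    "trains_per_second",
    "trains_to_table",
    "table_to_trains",
]


@dataclass(frozen=True)
class CrossWaveTrain:
    """One detected time-frequency similarity event and its characteristics."""

    time_s: float
    central_frequency_Hz: float
    psd: float
    duration_s: float
    duration_periods: float
    bandwidth_Hz: float
    phase_rad: float

    def __post_init__(self) -> None:
        if not (self.duration_s > 0 and self.bandwidth_Hz > 0):
            raise ValueError("duration and bandwidth must be positive")
        if abs(self.duration_periods - self.duration_s * self.central_frequency_Hz) > 1e-9 * max(
            1.0, abs(self.duration_periods)
        ):
            raise ValueError("duration_periods inconsistent with duration_s * frequency")
        if not -np.pi - 1e-12 <= self.phase_rad <= np.pi + 1e-12:
            raise ValueError("phase must lie in [-pi, pi]")


@dataclass(frozen=True)
class TrainFilter:
    """Attribute ranges selecting a kind of cross-wave train.

    Non-cyclic ranges are closed intervals [lo, hi].  The phase range is
    cyclic: ``phase_mode='include'`` keeps trains with phase in [lo, hi],
    ``'exclude'`` keeps the complement on the circle (e.g. the alternating
    pattern is phase exclude (-pi/2, +pi/2): everything nearer to +-pi than
    to 0).
    """

    freq: tuple = (0.0, np.inf)
    psd: tuple = (0.0, np.inf)
    duration_periods: tuple = (0.0, np.inf)
    bandwidth: tuple = (0.0, np.inf)
    phase: tuple = (-np.pi, np.pi)
    phase_mode: str = "include"

    def __post_init__(self) -> None:
        for name in ("freq", "psd", "duration_periods", "bandwidth"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} range has lo > hi")
        lo, hi = self.phase
        if not (-np.pi - 1e-12 <= lo <= np.pi + 1e-12 and -np.pi - 1e-12 <= hi <= np.pi + 1e-12):
            raise ValueError("phase bounds must lie in [-pi, pi]")
        if self.phase_mode not in ("include", "exclude"):
            raise ValueError("phase_mode must be 'include' or 'exclude'")

    def mask(self, table: pd.DataFrame) -> np.ndarray:
        """Boolean keep-mask over the rows of a train table."""
        f = table["central_frequency_Hz"].to_numpy(float)
        p = table["psd"].to_numpy(float)
        d = table["duration_periods"].to_numpy(float)
        b = table["bandwidth_Hz"].to_numpy(float)
        ph = table["phase_rad"].to_numpy(float)
        keep = (
            (self.freq[0] <= f) & (f <= self.freq[1])
            & (self.psd[0] <= p) & (p <= self.psd[1])
            & (self.duration_periods[0] <= d) & (d <= self.duration_periods[1])
            & (self.bandwidth[0] <= b) & (b <= self.bandwidth[1])
        )
        in_phase = (self.phase[0] <= ph) & (ph <= self.phase[1])
        return keep & (in_phase if self.phase_mode == "include" else ~in_phase)


@dataclass(frozen=True)
class DetectionConfig:
    """Detection knobs.

    half_power_fraction : fraction of the peak defining duration/bandwidth
        extents (0.5 = half power).
    exclude_coi : drop maxima inside the cone of influence.
    deduplicate : merge maxima falling within each other's half-power box.
    relative_floor : maxima below this fraction of the global |W| maximum are
        ignored (suppresses numerical noise on an exactly-zero background
        while preserving invariance to global amplitude rescaling).
    """

    half_power_fraction: float = 0.5
    exclude_coi: bool = True
    coi_multiplier: float = 1.0
    deduplicate: bool = True
    relative_floor: float = 1e-6


def _half_extent(values: np.ndarray, idx: int, threshold: float) -> tuple[int, int]:
    """Contiguous run [left, right] around idx where values >= threshold."""
    left = idx
    while left > 0 and values[left - 1] >= threshold:
        left -= 1
    right = idx
    while right < values.size - 1 and values[right + 1] >= threshold:
        right += 1
    return left, right


def measure_train(
    cws: CrossWaveletSpectrum,
    peak: tuple[int, int],
    half_power_fraction: float = 0.5,
) -> CrossWaveTrain:
    """Characterize one local maximum of |Wxy| at (time index, freq index)."""
    ti, fi = int(peak[0]), int(peak[1])
    power = cws.power
    pk = power[fi, ti]
    row = power[fi, :]
    col = power[:, ti]
    if (ti > 0 and row[ti - 1] > pk) or (ti < row.size - 1 and row[ti + 1] > pk) or (
        fi > 0 and col[fi - 1] > pk
    ) or (fi < col.size - 1 and col[fi + 1] > pk):
        raise ValueError(f"peak at (t={ti}, f={fi}) is not a local maximum")
    thr = half_power_fraction * pk
    t_left, t_right = _half_extent(row, ti, thr)
    f_left, f_right = _half_extent(col, fi, thr)
    dt = 1.0 / cws.fs
    df = float(cws.freqs[1] - cws.freqs[0]) if cws.freqs.size > 1 else float(cws.freqs[0])
    freq = float(cws.freqs[fi])
    duration_s = (t_right - t_left + 1) * dt
    bandwidth = float(cws.freqs[f_right] - cws.freqs[f_left]) + df
    return CrossWaveTrain(
        time_s=float(cws.times[ti]),
        central_frequency_Hz=freq,
        psd=float(pk),
        duration_s=duration_s,
        duration_periods=duration_s * freq,
        bandwidth_Hz=bandwidth,
        phase_rad=float(np.angle(cws.W[fi, ti])),
    )


def detect_cross_wave_trains(
    cws: CrossWaveletSpectrum, det: DetectionConfig = DetectionConfig()
) -> list[CrossWaveTrain]:
    """Detect and characterize all cross-wave trains of a spectrum.

    A candidate is a strict 8-neighborhood local maximum of |Wxy|; candidates
    inside the cone of influence or below the relative floor are dropped;
    overlapping candidates are deduplicated (stronger wins).  Returned sorted
    by peak time.
    """
    power = cws.power
    if power.shape[0] < 3 or power.shape[1] < 3:
        raise ValueError("spectrum too small for the 8-neighborhood maximum test")
    global_max = power.max()
    if global_max == 0:
        return []
    footprint = np.ones((3, 3), dtype=bool)
    footprint[1, 1] = False
    neighbor_max = ndimage.maximum_filter(power, footprint=footprint, mode="constant", cval=0.0)
    is_peak = power > neighbor_max
    is_peak &= power >= det.relative_floor * global_max
    # border cells cannot host a strict interior maximum
    is_peak[0, :] = is_peak[-1, :] = False
    is_peak[:, 0] = is_peak[:, -1] = False
    if det.exclude_coi:
        is_peak &= ~cws.coi_mask(det.coi_multiplier)
    fis, tis = np.nonzero(is_peak)
    trains = [
        measure_train(cws, (ti, fi), det.half_power_fraction) for fi, ti in zip(fis, tis)
    ]
    if det.deduplicate and len(trains) > 1:
        trains = _deduplicate(trains)
    return sorted(trains, key=lambda tr: (tr.time_s, tr.central_frequency_Hz))


def _deduplicate(trains: list[CrossWaveTrain]) -> list[CrossWaveTrain]:
    """Keep the strongest of any pair of trains lying inside each other's
    half-power time x frequency box."""
    ordered = sorted(trains, key=lambda tr: -tr.psd)
    kept: list[CrossWaveTrain] = []
    for tr in ordered:
        clash = False
        for acc in kept:
            if (
                abs(tr.time_s - acc.time_s) <= acc.duration_s / 2
                and abs(tr.central_frequency_Hz - acc.central_frequency_Hz)
                <= acc.bandwidth_Hz / 2
            ):
                clash = True
                break
        if not clash:
            kept.append(tr)
    return kept


def filter_trains(trains: list[CrossWaveTrain], f: TrainFilter) -> list[CrossWaveTrain]:
    """Trains whose every attribute lies inside the filter's ranges."""
    if not trains:
        return []
    mask = f.mask(trains_to_table(trains))
    return [tr for tr, keep in zip(trains, mask) if keep]


def trains_per_second(trains, total_duration_s: float) -> float:
    """Detected-train rate: count / recording duration."""
    if not total_duration_s > 0:
        raise ValueError("total_duration_s must be positive")
    return len(trains) / total_duration_s


def trains_to_table(trains: list[CrossWaveTrain], subject_id: str = "anon") -> pd.DataFrame:
    """Train list → train table (fixed column order, one row per train)."""
    rows = [{"subject_id": subject_id, **asdict(tr)} for tr in trains]
    if not rows:
        return pd.DataFrame(
            {c: pd.Series(dtype=(str if c == "subject_id" else float)) for c in TRAIN_COLUMNS}
        )
    return pd.DataFrame(rows)[TRAIN_COLUMNS]


def table_to_trains(table: pd.DataFrame) -> list[CrossWaveTrain]:
    """Train table → train list (subject_id column dropped)."""
    return [
        CrossWaveTrain(**{k: float(row[k]) for k in TRAIN_COLUMNS if k != "subject_id"})
        for _, row in table.iterrows()
    ]
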