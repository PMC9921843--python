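"""AUC diagrams over cross-wave train characteristics and filter fitting.

Each diagram compares the per-subject *rate* of cross-wave trains (trains per
second of recording, normalizing for recording length) passing a base filter
plus one swept attribute range, between the positive (PD) and negative (ET)
cohorts:

* attribute diagrams (frequency / PSD / duration / bandwidth): triangular,
  cell (lo, hi) counts trains with the attribute in [lo, hi];
* the Phase CWS AUC diagram is *two-triangle* because phase is cyclic: the
  upper triangle (hi > lo) counts trains with phase inside [lo, hi]; the
  lower triangle counts all trains *except* those in the cyclic range
  [ordinate, abscissa] (abscissa = upper excluded bound, ordinate = lower
  excluded bound), i.e. the complement ranges that a single triangle cannot
  express.

`fit_train_filter` sharpens a seed filter by greedy coordinate descent on the
ten range bounds, maximizing |AUC - 0.5| of the per-subject rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .phase_diagram import AUCDiagram
from .stats import mann_whitney_test, roc_auc
from .trains import TrainFilter

__all__ = [
    "CohortTrains",
    "FitConfig",
    "TrainFilterFit",
    "attribute_cws_auc_diagram",
    "phase_cws_auc_diagram",
    "fit_train_filter",
]

_ATTR_COLUMN = {
    "frequency": "central_frequency_Hz",
    "psd": "psd",
    "duration_periods": "duration_periods",
    "bandwidth": "bandwidth_Hz",
}


@dataclass
class CohortTrains:
    """Per-subject train tables with recording durations for one cohort."""

    tables: list[pd.DataFrame]
    durations_s: list[float]
    group: str = "other"

    def __post_init__(self) -> None:
        if len(self.tables) != len(self.durations_s):
            raise ValueError("one duration per subject table required")
        if any(d <= 0 for d in self.durations_s):
            raise ValueError("recording durations must be positive")

    def __len__(self) -> int:
        return len(self.tables)

    @classmethod
    def from_pairs(cls, pairs, freqs, group: str = "other", det=None, params=None):
        """Detect trains for every subject pair (convenience constructor)."""
        from .cws import MorletParams, cross_wavelet_spectrum
        from .trains import DetectionConfig, detect_cross_wave_trains, trains_to_table

        det = det or DetectionConfig()
        params = params or MorletParams()
        tables, durations = [], []
        for pair in pairs:
            spec = cross_wavelet_spectrum(pair, freqs, params)
            trains = detect_cross_wave_trains(spec, det)
            tables.append(trains_to_table(trains, subject_id=pair.subject_id))
            durations.append(pair.duration_s)
        return cls(tables=tables, durations_s=durations, group=group)


def _base_filtered_attrs(cohort: CohortTrains, base_filter: TrainFilter) -> list[pd.DataFrame]:
    out = []
    for table in cohort.tables:
        if len(table) == 0:
            out.append(table)
        else:
            out.append(table[base_filter.mask(table)])
    return out


def attribute_cws_auc_diagram(
    pos: CohortTrains,
    neg: CohortTrains,
    attribute: str,
    grid: np.ndarray,
    base_filter: TrainFilter = TrainFilter(),
) -> AUCDiagram:
    """Triangular AUC diagram over ranges of one train attribute.

    Cell (grid[i], grid[j]), j > i: each subject's score is the rate of
    trains passing ``base_filter`` with ``attribute`` in [grid[i], grid[j]];
    the cell holds roc_auc(positive scores, negative scores).
    """
    if attribute not in _ATTR_COLUMN:
        raise ValueError(f"attribute must be one of {sorted(_ATTR_COLUMN)}")
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both cohorts must be non-empty")
    grid = np.asarray(grid, dtype=float)
    if grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be ascending with at least 2 edges")
    col = _ATTR_COLUMN[attribute]
    subj_vals = [
        np.sort(t[col].to_numpy(float))
        for t in _base_filtered_attrs(pos, base_filter) + _base_filtered_attrs(neg, base_filter)
    ]
    durations = np.asarray(list(pos.durations_s) + list(neg.durations_s), dtype=float)
    n_pos = len(pos)
    n = grid.size
    matrix = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            counts = np.array(
                [
                    np.searchsorted(v, grid[j], side="right") - np.searchsorted(v, grid[i], side="left")
                    for v in subj_vals
                ],
                dtype=float,
            )
            scores = counts / durations
            matrix[j, i] = roc_auc(scores[:n_pos], scores[n_pos:])
    return AUCDiagram(
        grid, grid, matrix, axis_kind="frequency",
        metadata={
            "n_pos": n_pos, "n_neg": len(neg),
            "score": f"trains_per_second[{attribute}]",
        },
    )


def _phase_counts(phases: np.ndarray, lo: float, hi: float, exclude: bool) -> int:
    inside = np.count_nonzero((phases >= lo) & (phases <= hi))
    return phases.size - inside if exclude else inside


def phase_cws_auc_diagram(
    pos: CohortTrains,
    neg: CohortTrains,
    base_filter: TrainFilter = TrainFilter(),
    grid: np.ndarray | None = None,
) -> AUCDiagram:
    """Two-triangle AUC diagram over cyclic phase ranges (see module docs)."""
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both cohorts must be non-empty")
    if grid is None:
        grid = np.linspace(-np.pi, np.pi, 41)  # pi/20 step
    grid = np.asarray(grid, dtype=float)
    if np.any(grid < -np.pi - 1e-9) or np.any(grid > np.pi + 1e-9):
        raise ValueError("phase grid must lie inside [-pi, pi]")
    if grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be ascending with at least 2 edges")
    subj_phases = [
        t["phase_rad"].to_numpy(float)
        for t in _base_filtered_attrs(pos, base_filter) + _base_filtered_attrs(neg, base_filter)
    ]
    durations = np.asarray(list(pos.durations_s) + list(neg.durations_s), dtype=float)
    n_pos = len(pos)
    n = grid.size
    matrix = np.full((n, n), np.nan)
    for i in range(n):  # abscissa index
        for j in range(n):  # ordinate index
            if i == j:
                continue
            if j > i:  # upper triangle: include [grid[i], grid[j]]
                lo, hi, exclude = grid[i], grid[j], False
            else:  # lower triangle: exclude [grid[j], grid[i]]
                lo, hi, exclude = grid[j], grid[i], True
            counts = np.array(
                [_phase_counts(ph, lo, hi, exclude) for ph in subj_phases], dtype=float
            )
            scores = counts / durations
            matrix[j, i] = roc_auc(scores[:n_pos], scores[n_pos:])
    return AUCDiagram(
        grid, grid, matrix, axis_kind="phase_two_triangle",
        metadata={"n_pos": n_pos, "n_neg": len(neg), "score": "trains_per_second[phase]"},
    )


# ---------------------------------------------------------------------------
# iterative train-filter fitting

_SWEEP_ORDER = [
    ("freq", 0), ("freq", 1),
    ("psd", 0), ("psd", 1),
    ("duration_periods", 0), ("duration_periods", 1),
    ("bandwidth", 0), ("bandwidth", 1),
    ("phase", 0), ("phase", 1),
]


@dataclass(frozen=True)
class FitConfig:
    """Grids and schedule of the greedy coordinate-descent filter fit.

    Any grid left as None is derived from the pooled train attributes
    (``n_grid`` evenly spaced values spanning the data, plus the phase grid
    default of step pi/20).
    """

    freq_grid: np.ndarray | None = None
    psd_grid: np.ndarray | None = None
    duration_grid: np.ndarray | None = None
    bandwidth_grid: np.ndarray | None = None
    phase_grid: np.ndarray | None = None
    n_grid: int = 25
    max_sweeps: int = 50


@dataclass
class TrainFilterFit:
    """Result of :func:`fit_train_filter` (fitted filter + diagnostics)."""

    filter: TrainFilter
    auc: float
    pvalue: float
    objective_trace: list
    n_sweeps: int
    scores_pos: np.ndarray
    scores_neg: np.ndarray

    @property
    def objective(self) -> float:
        return abs(self.auc - 0.5)

    def summary(self) -> str:
        f = self.filter
        lines = [
            "Cross-wave train filter fit",
            "===========================",
            f"frequency range      : {f.freq[0]:.4g} - {f.freq[1]:.4g} Hz",
            f"PSD range            : {f.psd[0]:.4g} - {f.psd[1]:.4g}",
            f"duration range       : {f.duration_periods[0]:.4g} - {f.duration_periods[1]:.4g} periods",
            f"bandwidth range      : {f.bandwidth[0]:.4g} - {f.bandwidth[1]:.4g} Hz",
            f"phase range ({f.phase_mode:7s}): {f.phase[0]:+.3f} - {f.phase[1]:+.3f} rad",
            f"AUC                  : {self.auc:.4f}",
            f"Mann-Whitney p       : {self.pvalue:.4g}",
            f"sweeps               : {self.n_sweeps}",
            f"n (pos, neg)         : {self.scores_pos.size}, {self.scores_neg.size}",
        ]
        return "\n".join(lines)


def _derive_grid(values: np.ndarray, given, n_grid: int) -> np.ndarray:
    if given is not None:
        g = np.asarray(given, dtype=float)
        if g.size < 2 or np.any(np.diff(g) <= 0):
            raise ValueError("fit grids must be ascending with >= 2 values")
        return g
    lo, hi = float(values.min()), float(values.max())
    if hi <= lo:
        hi = lo + 1.0
    return np.linspace(lo, hi, n_grid)


def _snap(grid: np.ndarray, value: float) -> int:
    return int(np.argmin(np.abs(grid - value)))


def fit_train_filter(
    pos: CohortTrains,
    neg: CohortTrains,
    init: TrainFilter = TrainFilter(),
    schedule: FitConfig = FitConfig(),
) -> TrainFilterFit:
    """Greedy coordinate-descent fit of a train filter separating the cohorts.

    Each of the ten range bounds in turn is moved by one grid step (either
    direction) and the move is accepted if it increases |AUC - 0.5| of the
    per-subject trains-per-second scores; at an exactly tied objective the
    wider range is preferred (less overfit).  Terminates when a full sweep
    accepts no move or after ``max_sweeps``.  Deterministic: no randomness.
    """
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both cohorts must be non-empty")
    tables = list(pos.tables) + list(neg.tables)
    durations = np.asarray(list(pos.durations_s) + list(neg.durations_s), dtype=float)
    n_pos = len(pos)
    pooled = pd.concat([t for t in tables if len(t)], ignore_index=True) if any(
        len(t) for t in tables
    ) else None
    if pooled is None or len(pooled) == 0:
        raise ValueError("no trains in either cohort: nothing to fit")

    grids = {
        "freq": _derive_grid(
            pooled["central_frequency_Hz"].to_numpy(float), schedule.freq_grid, schedule.n_grid
        ),
        "psd": _derive_grid(pooled["psd"].to_numpy(float), schedule.psd_grid, schedule.n_grid),
        "duration_periods": _derive_grid(
            pooled["duration_periods"].to_numpy(float), schedule.duration_grid, schedule.n_grid
        ),
        "bandwidth": _derive_grid(
            pooled["bandwidth_Hz"].to_numpy(float), schedule.bandwidth_grid, schedule.n_grid
        ),
        "phase": (
            np.asarray(schedule.phase_grid, dtype=float)
            if schedule.phase_grid is not None
            else np.linspace(-np.pi, np.pi, 41)
        ),
    }

    # bound state as grid indices; infinite init bounds snap to the grid ends
    state: dict[str, list[int]] = {}
    for name, grid in grids.items():
        lo, hi = getattr(init, name)
        ilo = 0 if not np.isfinite(lo) else _snap(grid, lo)
        ihi = grid.size - 1 if not np.isfinite(hi) else _snap(grid, hi)
        if ilo > ihi:
            ilo, ihi = ihi, ilo
        state[name] = [ilo, ihi]

    def build(st: dict) -> TrainFilter:
        return TrainFilter(
            freq=(grids["freq"][st["freq"][0]], grids["freq"][st["freq"][1]]),
            psd=(grids["psd"][st["psd"][0]], grids["psd"][st["psd"][1]]),
            duration_periods=(
                grids["duration_periods"][st["duration_periods"][0]],
                grids["duration_periods"][st["duration_periods"][1]],
            ),
            bandwidth=(
                grids["bandwidth"][st["bandwidth"][0]],
                grids["bandwidth"][st["bandwidth"][1]],
            ),
            phase=(grids["phase"][st["phase"][0]], grids["phase"][st["phase"][1]]),
            phase_mode=init.phase_mode,
        )

    def scores_of(f: TrainFilter) -> np.ndarray:
        counts = np.array(
            [0 if len(t) == 0 else int(np.count_nonzero(f.mask(t))) for t in tables],
            dtype=float,
        )
        return counts / durations

    def objective_of(f: TrainFilter) -> tuple[float, float]:
        s = scores_of(f)
        auc = roc_auc(s[:n_pos], s[n_pos:])
        return abs(auc - 0.5), auc

    current = build(state)
    obj, auc = objective_of(current)
    trace = [obj]
    sweeps = 0
    for sweeps in range(1, schedule.max_sweeps + 1):
        improved = False
        for name, side in _SWEEP_ORDER:
            grid = grids[name]
            ilo, ihi = state[name]
            idx = state[name][side]
            for step in (-1, 1):
                cand = idx + step
                if cand < 0 or cand > grid.size - 1:
                    continue
                if side == 0 and cand > ihi:
                    continue
                if side == 1 and cand < ilo:
                    continue
                trial = {k: list(v) for k, v in state.items()}
                trial[name][side] = cand
                f_trial = build(trial)
                obj_t, auc_t = objective_of(f_trial)
                widens = (side == 0 and cand < idx) or (side == 1 and cand > idx)
                if obj_t > obj + 1e-12 or (abs(obj_t - obj) <= 1e-12 and widens):
                    accept_improves = obj_t > obj + 1e-12
                    state = trial
                    current = f_trial
                    obj, auc = obj_t, auc_t
                    if accept_improves:
                        trace.append(obj)
                        improved = True
                    idx = cand
                    ilo, ihi = state[name]
        if not improved:
            break

    s = scores_of(current)
    _, pvalue = mann_whitney_test(s[:n_pos], s[n_pos:])
    return TrainFilterFit(
        filter=current,
        auc=auc,
        pvalue=pvalue,
        objective_trace=trace,
        n_sweeps=sweeps,
        scores_pos=s[:n_pos],
        scores_neg=s[n_pos:],
    )
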