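"""Phase-difference AUC diagrams over a triangular frequency-range grid.

An AUC diagram answers "in which frequency range does a per-subject score
separate the two diagnostic groups?" without choosing the range in advance.
The abscissa is the lower band edge (MinFreq), the ordinate the upper edge
(MaxFreq); every cell with MaxFreq > MinFreq holds the ROC AUC of the
per-subject score computed in that band (here: the mean flexor-extensor
phase difference), so the diagram is triangular.  Cells near 0 or 1 mark
discriminative ranges; 0.5 is uninformative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .phase import FrequencyRange, band_mean_phase_difference
from .preprocess import TremorPair
from .stats import roc_auc

__all__ = ["AUCDiagram", "phase_diff_auc_diagram", "extreme_cells"]


@dataclass
class AUCDiagram:
    """Matrix of AUC values over parameter-range grids.

    ``matrix[j, i]`` is the AUC for the range (x_axis[i], y_axis[j]); cells
    outside the valid domain are NaN.  ``axis_kind`` is ``frequency``
    (triangular: defined only for upper > lower) or ``phase_two_triangle``
    (cyclic phase ranges; the lower triangle holds complement ranges).
    """

    x_axis: np.ndarray
    y_axis: np.ndarray
    matrix: np.ndarray
    axis_kind: str = "frequency"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.x_axis = np.asarray(self.x_axis, dtype=float)
        self.y_axis = np.asarray(self.y_axis, dtype=float)
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (self.y_axis.size, self.x_axis.size):
            raise ValueError("matrix shape must be (len(y_axis), len(x_axis))")
        defined = self.matrix[np.isfinite(self.matrix)]
        if defined.size and (defined.min() < -1e-12 or defined.max() > 1 + 1e-12):
            raise ValueError("AUC values must lie in [0, 1]")

    @property
    def defined_mask(self) -> np.ndarray:
        return np.isfinite(self.matrix)

    def complement(self) -> "AUCDiagram":
        """The diagram obtained by swapping the two cohorts (1 - AUC)."""
        return AUCDiagram(
            self.x_axis, self.y_axis, 1.0 - self.matrix, self.axis_kind, dict(self.metadata)
        )

    def plot(self, ax=None, title: str | None = None):
        """Render with the jet colormap anchored to [0, 1] (blue→0, green 0.5,
        red→1)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        mesh = ax.pcolormesh(
            self.x_axis, self.y_axis, self.matrix, cmap="jet", vmin=0.0, vmax=1.0
        )
        ax.figure.colorbar(mesh, ax=ax, label="AUC")
        unit = "Hz" if self.axis_kind == "frequency" else "rad"
        ax.set_xlabel(f"range lower bound ({unit})")
        ax.set_ylabel(f"range upper bound ({unit})")
        if title:
            ax.set_title(title)
        return ax


def phase_diff_auc_diagram(
    pos_cohort: list[TremorPair],
    neg_cohort: list[TremorPair],
    grid: np.ndarray,
    order: int = 8,
    mode: str = "as_printed",
    averaging: str = "arithmetic",
    edge_fraction: float = 0.05,
) -> AUCDiagram:
    """Phase-difference AUC diagram over all bands (grid[i], grid[j]), j > i.

    For every valid cell each subject's envelopes are band-passed and the mean
    phase difference taken as the score; the cell value is the ROC AUC of
    positive (PD) vs negative (ET) scores.  Bands whose filter design is
    numerically unstable are left undefined rather than aborting the sweep.
    """
    if not pos_cohort or not neg_cohort:
        raise ValueError("both cohorts must be non-empty")
    grid = np.asarray(grid, dtype=float)
    if grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be an ascending array of at least 2 edges")
    fs = pos_cohort[0].fs
    for p in list(pos_cohort) + list(neg_cohort):
        if p.fs != fs:
            raise ValueError("all subjects must share one sampling rate")
    if grid[-1] >= fs / 2:
        raise ValueError(f"grid exceeds Nyquist ({fs / 2} Hz)")
    if grid[0] <= 0:
        raise ValueError("grid must be strictly positive")

    n = grid.size
    matrix = np.full((n, n), np.nan)
    subjects = list(pos_cohort) + list(neg_cohort)
    n_pos = len(pos_cohort)
    for i in range(n):  # lower bound index (abscissa)
        for j in range(i + 1, n):  # upper bound index (ordinate)
            band = FrequencyRange(grid[i], grid[j])
            scores = np.empty(len(subjects))
            ok = True
            for k, pair in enumerate(subjects):
                try:
                    scores[k] = band_mean_phase_difference(
                        pair, band, order=order, mode=mode,
                        averaging=averaging, edge_fraction=edge_fraction,
                    )
                except ValueError:
                    ok = False
                    break
            if ok:
                matrix[j, i] = roc_auc(scores[:n_pos], scores[n_pos:])
    return AUCDiagram(
        grid,
        grid,
        matrix,
        axis_kind="frequency",
        metadata={
            "n_pos": n_pos,
            "n_neg": len(neg_cohort),
            "score": "band_mean_phase_difference",
            "mode": mode,
            "averaging": averaging,
            "order": order,
        },
    )


def extreme_cells(d: AUCDiagram, k: int = 1) -> list[tuple[tuple[float, float], float]]:
    """The k defined cells maximizing |AUC - 0.5|, sorted descending.

    Ties are broken by (lower bound, upper bound) ascending.  Returns
    ``[((lo, hi), auc), ...]``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    jj, ii = np.nonzero(d.defined_mask)
    if jj.size == 0:
        raise ValueError("diagram has no defined cells")
    cells = [
        (float(d.x_axis[i]), float(d.y_axis[j]), float(d.matrix[j, i])) for j, i in zip(jj, ii)
    ]
    cells.sort(key=lambda c: (-abs(c[2] - 0.5), c[0], c[1]))
    return [((lo, hi), auc) for lo, hi, auc in cells[:k]]
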