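import numpy as np
import pandas as pd
import pytest

from crosswave.cws_diagrams import (
    CohortTrains,
    FitConfig,
    attribute_cws_auc_diagram,
    fit_train_filter,
    phase_cws_auc_diagram,
)
from crosswave.stats import roc_auc
from crosswave.trains import TrainFilter

DUR = 90.0


def synth_table(rng, n_band=0, band=(4.0, 6.0), phase_center=None, n_bg=40):
    """Synthetic train table: optional planted band plus broadband background."""
    rows = []
    for _ in range(n_band):
        f = rng.uniform(*band)
        phase = (
            rng.uniform(-np.pi, np.pi)
            if phase_center is None
            else float(np.clip(rng.normal(phase_center, 0.2), -np.pi, np.pi))
        )
        rows.append(dict(subject_id="s", time_s=rng.uniform(0, DUR), central_frequency_Hz=f,
                         psd=rng.uniform(5, 50), duration_s=1.0, duration_periods=f,
                         bandwidth_Hz=rng.uniform(0.5, 1.2), phase_rad=phase))
    for _ in range(n_bg):
        f = rng.uniform(8.0, 40.0)
        rows.append(dict(subject_id="s", time_s=rng.uniform(0, DUR), central_frequency_Hz=f,
                         psd=rng.uniform(1, 20), duration_s=0.5, duration_periods=0.5 * f,
                         bandwidth_Hz=rng.uniform(1, 5), phase_rad=rng.uniform(-np.pi, np.pi)))
    cols = ["subject_id", "time_s", "central_frequency_Hz", "psd", "duration_s",
            "duration_periods", "bandwidth_Hz", "phase_rad"]
    return pd.DataFrame(rows, columns=cols)


@pytest.fixture
def planted_cohorts(rng):
    pos = CohortTrains(
        [synth_table(rng, n_band=rng.poisson(30), phase_center=np.pi) for _ in range(10)],
        [DUR] * 10, "PD",
    )
    neg = CohortTrains([synth_table(rng) for _ in range(10)], [DUR] * 10, "ET")
    return pos, neg


GRID = np.arange(2.0, 42.0, 2.0)


class TestAttributeDiagram:
    def test_planted_band_cell_extreme(self, planted_cohorts):
        pos, neg = planted_cohorts
        d = attribute_cws_auc_diagram(pos, neg, "frequency", GRID)
        i = list(GRID).index(4.0)
        j = list(GRID).index(6.0)
        assert d.matrix[j, i] >= 0.9

    def test_cohort_swap_complement(self, planted_cohorts):
        pos, neg = planted_cohorts
        fwd = attribute_cws_auc_diagram(pos, neg, "frequency", GRID)
        rev = attribute_cws_auc_diagram(neg, pos, "frequency", GRID)
        mask = fwd.defined_mask
        # exact on the rational pair-counts; float division leaves <= 1 ulp
        np.testing.assert_allclose(rev.matrix[mask], 1.0 - fwd.matrix[mask],
                                   rtol=0, atol=1e-15)

    def test_full_range_single_cell_equals_total_rate_auc(self, planted_cohorts):
        pos, neg = planted_cohorts
        grid = np.array([0.0, 100.0])
        d = attribute_cws_auc_diagram(pos, neg, "frequency", grid)
        rates_pos = [len(t) / DUR for t in pos.tables]
        rates_neg = [len(t) / DUR for t in neg.tables]
        assert d.matrix[1, 0] == roc_auc(rates_pos, rates_neg)

    def test_unknown_attribute_rejected(self, planted_cohorts):
        pos, neg = planted_cohorts
        with pytest.raises(ValueError, match="attribute"):
            attribute_cws_auc_diagram(pos, neg, "sparkle", GRID)

    def test_null_cohorts_calibrated(self, rng):
        pos = CohortTrains([synth_table(rng) for _ in range(10)], [DUR] * 10, "A")
        neg = CohortTrains([synth_table(rng) for _ in range(10)], [DUR] * 10, "B")
        d = attribute_cws_auc_diagram(pos, neg, "frequency", GRID)
        devs = np.abs(d.matrix[d.defined_mask] - 0.5)
        assert np.mean(devs <= 0.25) >= 0.9


class TestPhaseDiagram:
    def test_include_exclude_partition_per_subject(self, rng):
        table = synth_table(rng, n_band=20, phase_center=None)
        phases = table["phase_rad"].to_numpy()
        a, b = -1.0, 1.5
        inside = np.count_nonzero((phases >= a) & (phases <= b))
        outside = np.count_nonzero(~((phases >= a) & (phases <= b)))
        assert inside + outside == len(table)

    def test_full_phase_cell_matches_attribute_diagram(self, planted_cohorts):
        pos, neg = planted_cohorts
        grid = np.array([-np.pi, 0.0, np.pi])
        d = phase_cws_auc_diagram(pos, neg, grid=grid)
        full = attribute_cws_auc_diagram(pos, neg, "frequency", np.array([0.0, 100.0]))
        assert d.matrix[2, 0] == full.matrix[1, 0]

    def test_alternating_cohort_red_near_pi(self, planted_cohorts):
        pos, neg = planted_cohorts
        d = phase_cws_auc_diagram(pos, neg, TrainFilter(freq=(4.0, 6.0)))
        g = d.x_axis
        i = int(np.argmin(np.abs(g - 2.5)))
        assert d.matrix[len(g) - 1, i] >= 0.9  # include [2.5, pi]
        i0 = int(np.argmin(np.abs(g + 0.5)))
        j0 = int(np.argmin(np.abs(g - 0.5)))
        assert d.matrix[j0, i0] <= 0.6  # include [-0.5, 0.5]: no planted mass

    def test_lower_triangle_is_cyclic_complement(self, planted_cohorts):
        pos, neg = planted_cohorts
        grid = np.linspace(-np.pi, np.pi, 9)
        d = phase_cws_auc_diagram(pos, neg, TrainFilter(freq=(4.0, 6.0)), grid=grid)
        # excluding the in-phase range keeps the planted anti-phase trains
        j = int(np.argmin(np.abs(grid + 1.0)))  # ordinate: lower excluded bound
        i = int(np.argmin(np.abs(grid - 1.0)))  # abscissa: upper excluded bound
        assert d.matrix[j, i] >= 0.9

    def test_grid_outside_circle_rejected(self, planted_cohorts):
        pos, neg = planted_cohorts
        with pytest.raises(ValueError, match="pi"):
            phase_cws_auc_diagram(pos, neg, grid=np.array([-4.0, 0.0, 4.0]))

    def test_cohort_swap_complement(self, planted_cohorts):
        pos, neg = planted_cohorts
        grid = np.linspace(-np.pi, np.pi, 9)
        fwd = phase_cws_auc_diagram(pos, neg, grid=grid)
        rev = phase_cws_auc_diagram(neg, pos, grid=grid)
        mask = fwd.defined_mask
        # exact on the rational pair-counts; float division leaves <= 1 ulp
        np.testing.assert_allclose(rev.matrix[mask], 1.0 - fwd.matrix[mask],
                                   rtol=0, atol=1e-15)


class TestFitting:
    def test_recovers_planted_band(self, planted_cohorts):
        pos, neg = planted_cohorts
        fit = fit_train_filter(pos, neg, TrainFilter(freq=(3.0, 8.0)))
        lo, hi = fit.filter.freq
        assert lo <= 6.0 and hi >= 4.0  # fitted range overlaps the planted band
        assert fit.auc >= 0.95

    def test_objective_trace_non_decreasing(self, planted_cohorts):
        pos, neg = planted_cohorts
        fit = fit_train_filter(pos, neg, TrainFilter(freq=(3.0, 8.0)))
        trace = fit.objective_trace
        assert all(a <= b + 1e-12 for a, b in zip(trace, trace[1:]))

    def test_identical_cohorts_stay_near_half(self, rng):
        tables = [synth_table(rng) for _ in range(10)]
        pos = CohortTrains(tables, [DUR] * 10, "A")
        neg = CohortTrains([t.copy() for t in tables], [DUR] * 10, "B")
        fit = fit_train_filter(pos, neg)
        assert fit.objective <= 0.15

    def test_deterministic(self, planted_cohorts):
        pos, neg = planted_cohorts
        f1 = fit_train_filter(pos, neg, TrainFilter(freq=(3.0, 8.0)))
        f2 = fit_train_filter(pos, neg, TrainFilter(freq=(3.0, 8.0)))
        assert f1.filter == f2.filter and f1.auc == f2.auc

    def test_no_trains_anywhere_rejected(self):
        empty = synth_table(np.random.default_rng(0), n_bg=0)
        pos = CohortTrains([empty], [DUR], "A")
        neg = CohortTrains([empty.copy()], [DUR], "B")
        with pytest.raises(ValueError, match="no trains"):
            fit_train_filter(pos, neg)

    def test_summary_mentions_fitted_range(self, planted_cohorts):
        pos, neg = planted_cohorts
        fit = fit_train_filter(pos, neg, TrainFilter(freq=(3.0, 8.0)))
        text = fit.summary()
        assert "AUC" in text and "frequency range" in text
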