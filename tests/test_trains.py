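import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crosswave.cws import cross_wavelet_spectrum, frequency_grid
from crosswave.preprocess import TremorPair
from crosswave.trains import (
    CrossWaveTrain,
    DetectionConfig,
    TrainFilter,
    detect_cross_wave_trains,
    filter_trains,
    measure_train,
    trains_per_second,
    trains_to_table,
)
from tests.conftest import burst_pair

FS = 125.0
GRID = frequency_grid(2.0, 20.0, 0.1)


def make_train(freq=5.0, psd=100.0, periods=1.4, bw=0.9, phase=-3.0, time_s=10.0):
    return CrossWaveTrain(
        time_s=time_s,
        central_frequency_Hz=freq,
        psd=psd,
        duration_s=periods / freq,
        duration_periods=periods,
        bandwidth_Hz=bw,
        phase_rad=phase,
    )


class TestDetection:
    def test_single_planted_burst_gives_one_train(self):
        pair = burst_pair(freq=5.0, offset=-3.0, onsets=(14.0,), duration_s=30.0)
        trains = detect_cross_wave_trains(cross_wavelet_spectrum(pair, GRID))
        assert len(trains) == 1
        tr = trains[0]
        assert tr.central_frequency_Hz == pytest.approx(5.0, abs=0.3)
        assert tr.phase_rad == pytest.approx(-3.0, abs=0.3)
        assert tr.time_s == pytest.approx(15.0, abs=0.5)

    def test_constant_signals_give_no_trains(self):
        pair = TremorPair(np.zeros(2000), np.zeros(2000), FS)
        spec = cross_wavelet_spectrum(pair, GRID)
        assert detect_cross_wave_trains(spec) == []

    def test_two_separated_bursts_ordered_in_time(self):
        pair = burst_pair(freq=5.0, onsets=(10.0, 20.0), duration_s=40.0)
        trains = detect_cross_wave_trains(cross_wavelet_spectrum(pair, GRID))
        assert len(trains) == 2
        assert trains[0].time_s < trains[1].time_s
        assert trains[1].time_s - trains[0].time_s == pytest.approx(10.0, abs=1.0)

    def test_every_peak_dominates_neighbors(self, rng):
        pair = TremorPair(np.abs(rng.normal(size=3000)) + 1,
                          np.abs(rng.normal(size=3000)) + 1, FS)
        spec = cross_wavelet_spectrum(pair, frequency_grid(2.0, 20.0, 0.5))
        power = spec.power
        dt = 1 / FS
        df = spec.freqs[1] - spec.freqs[0]
        for tr in detect_cross_wave_trains(spec):
            ti = int(round(tr.time_s / dt))
            fi = int(round((tr.central_frequency_Hz - spec.freqs[0]) / df))
            patch = power[fi - 1 : fi + 2, ti - 1 : ti + 2]
            assert power[fi, ti] == patch.max()

    def test_detection_invariant_to_rescaling(self, rng):
        fx = np.abs(rng.normal(size=3000)) + 1
        ex = np.abs(rng.normal(size=3000)) + 1
        freqs = frequency_grid(2.0, 20.0, 0.5)
        t1 = detect_cross_wave_trains(cross_wavelet_spectrum(TremorPair(fx, ex, FS), freqs))
        t2 = detect_cross_wave_trains(
            cross_wavelet_spectrum(TremorPair(7.5 * fx, 7.5 * ex, FS), freqs)
        )
        assert len(t1) == len(t2)
        assert [a.time_s for a in t1] == [b.time_s for b in t2]

    def test_parameter_recovery_over_seeded_bursts(self, rng):
        freq_errs, phase_errs = [], []
        grid = frequency_grid(1.5, 35.0, 0.1)
        for _ in range(20):
            f = rng.uniform(3.0, 30.0)
            phi = rng.uniform(-np.pi, np.pi)
            pair = burst_pair(freq=f, offset=phi, onsets=(12.0,), burst_duration_s=2.0,
                              duration_s=25.0)
            trains = detect_cross_wave_trains(cross_wavelet_spectrum(pair, grid))
            assert trains, f"burst at {f:.2f} Hz not detected"
            best = max(trains, key=lambda tr: tr.psd)
            freq_errs.append(abs(best.central_frequency_Hz - f))
            d = abs(best.phase_rad - phi)
            phase_errs.append(min(d, 2 * np.pi - d))
        assert np.median(freq_errs) <= 0.3
        assert np.median(phase_errs) <= 0.3

    def test_tiny_spectrum_rejected(self):
        pair = burst_pair(duration_s=30.0)
        spec = cross_wavelet_spectrum(pair, np.array([4.0, 5.0]))
        with pytest.raises(ValueError, match="too small"):
            detect_cross_wave_trains(spec)


class TestMeasurement:
    def test_duration_matches_gaussian_envelope_width(self):
        # Gaussian burst envelope with sigma = D/6: the envelope's half-maximum
        # width is 2*sigma*sqrt(2 ln 2); cross power is envelope^2, so the
        # half-power width is 2*sigma*sqrt(ln 2)
        sigma = 2.0 / 6.0
        pair = burst_pair(freq=5.0, onsets=(14.0,), burst_duration_s=2.0,
                          duration_s=30.0, window="gaussian")
        trains = detect_cross_wave_trains(cross_wavelet_spectrum(pair, GRID))
        best = max(trains, key=lambda tr: tr.psd)
        expected = 2 * sigma * np.sqrt(np.log(2))
        assert best.duration_s == pytest.approx(expected, rel=0.15)

    def test_duration_periods_definitional(self):
        pair = burst_pair(freq=5.0, onsets=(14.0,), duration_s=30.0)
        (tr,) = detect_cross_wave_trains(cross_wavelet_spectrum(pair, GRID))
        assert tr.duration_periods == tr.duration_s * tr.central_frequency_Hz

    def test_non_maximum_peak_rejected(self):
        pair = burst_pair(freq=5.0, onsets=(14.0,), duration_s=30.0)
        spec = cross_wavelet_spectrum(pair, GRID)
        flat = np.unravel_index(np.argmax(spec.power), spec.power.shape)
        off_peak = (int(flat[1]) + 40, int(flat[0]))
        with pytest.raises(ValueError, match="not a local maximum"):
            measure_train(spec, off_peak)


class TestFiltering:
    def test_all_pass_filter_is_identity(self):
        trains = [make_train(), make_train(freq=13.0, phase=0.3, time_s=20.0)]
        assert filter_trains(trains, TrainFilter()) == trains

    def test_include_exclude_partition(self, rng):
        trains = [
            make_train(freq=rng.uniform(2, 20), phase=rng.uniform(-np.pi, np.pi), time_s=i)
            for i in range(30)
        ]
        inc = TrainFilter(phase=(-1.0, 2.0), phase_mode="include")
        exc = TrainFilter(phase=(-1.0, 2.0), phase_mode="exclude")
        assert len(filter_trains(trains, inc)) + len(filter_trains(trains, exc)) == 30

    def test_parkinsonian_alternating_preset_row(self):
        # 4-6 Hz / PSD 2-4500 / 1-5 periods / 0.5-1.2 Hz / phase free
        row = TrainFilter(freq=(4, 6), psd=(2, 4500), duration_periods=(1, 5),
                          bandwidth=(0.5, 1.2), phase=(-np.pi, np.pi))
        keep = make_train(freq=5.0, psd=100.0, periods=1.4, bw=0.9, phase=-3.0)
        drop = make_train(freq=13.7, psd=3.86, periods=0.87, bw=2.6, phase=0.3)
        assert filter_trains([keep, drop], row) == [keep]

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.floats(0, 2), st.floats(0, 2))
    def test_widening_never_drops_trains(self, expand_lo, expand_hi):
        trains = [make_train(freq=f, time_s=f) for f in np.linspace(2, 20, 19)]
        narrow = TrainFilter(freq=(6.0, 10.0))
        wide = TrainFilter(freq=(6.0 - expand_lo, 10.0 + expand_hi))
        assert len(filter_trains(trains, wide)) >= len(filter_trains(trains, narrow))


class TestRate:
    def test_zero_trains(self):
        assert trains_per_second([], 60.0) == 0.0

    def test_three_per_minute(self):
        trains = [make_train(time_s=t) for t in (1.0, 2.0, 3.0)]
        assert trains_per_second(trains, 60.0) == pytest.approx(0.05)

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            trains_per_second([], 0.0)

    def test_planted_rate_recovered(self):
        from crosswave.synthetic import TremorSpec, simulate_tremor_pair

        rate = 0.3
        spec = TremorSpec(burst_freq=5.0, burst_rate=rate, burst_duration_s=1.0,
                          burst_amplitude=20.0, noise_sd=0.0, amplitude_jitter=0.0,
                          duration_s=90.0)
        pair = simulate_tremor_pair(spec, seed=11)
        cws = cross_wavelet_spectrum(pair, frequency_grid(3.0, 8.0, 0.1))
        trains = [
            t for t in detect_cross_wave_trains(cws)
            if 4.0 <= t.central_frequency_Hz <= 6.0
        ]
        measured = trains_per_second(trains, pair.duration_s)
        assert abs(measured - rate) <= 3 * np.sqrt(rate / 90.0)


class TestTable:
    def test_round_trip_through_table(self):
        trains = [make_train(), make_train(freq=13.0, phase=0.3, time_s=20.0)]
        from crosswave.trains import table_to_trains

        assert table_to_trains(trains_to_table(trains)) == trains
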