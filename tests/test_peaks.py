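"""Gating, peak detection and single-Gaussian fitting."""

import warnings

import numpy as np
import pytest

from peflow import (
    EventTable,
    FcmHistogram,
    PISUM,
    SimulationParams,
    bin_events,
    detect_peaks,
    fit_peak,
    gate_events,
    simulate_sample,
)
from peflow.errors import EmptyGateError, FitError, NoPeaksError, ParameterError
from peflow.peaks import GaussianPeakDetector


class TestGating:
    def test_full_range_gate_is_identity(self, ustulata_events):
        g = gate_events(ustulata_events, fl_range=(0.0, 1e9))
        assert len(g) == len(ustulata_events)

    def test_gate_below_median_returns_exact_subset(self, ustulata_events):
        med = float(np.median(ustulata_events.fluorescence))
        g = gate_events(ustulata_events, fl_range=(0.0, med))
        expected = (ustulata_events.fluorescence < med).sum()
        assert len(g) == expected

    def test_debris_exclusion_recovers_mixture_fraction(self):
        p = SimulationParams(
            two_c_pg=15.7, p_pg=3.55, standard=PISUM,
            debris_fraction=0.2, seed=3,
        )
        t = simulate_sample(p)
        std_pos = PISUM.two_c_pg / p.gain_pg_per_channel
        cut = std_pos * (1 - 3.5 * p.cv)
        g = gate_events(t, fl_range=(cut, 1e9))
        retained = len(g) / len(t)
        se = np.sqrt(0.8 * 0.2 / 5000)
        assert retained == pytest.approx(0.8, abs=5 * se)

    def test_ssc_gate_requires_side_scatter(self):
        t = EventTable(np.array([1.0, 2.0]))
        with pytest.raises(ParameterError):
            gate_events(t, ssc_range=(0, 1))

    def test_empty_gate_errors(self, ustulata_events):
        with pytest.raises(EmptyGateError):
            gate_events(ustulata_events, fl_range=(1e8, 1e9))

    def test_gate_recorded_in_meta(self, ustulata_events):
        g = gate_events(ustulata_events, fl_range=(0.0, 1e9))
        assert g.meta["gate"]["fl"] == (0.0, 1e9)


class TestFitPeak:
    @staticmethod
    def _gauss_hist(mu=200.0, sd=6.0, area=2000, n_channels=1024, seed=0):
        rng = np.random.default_rng(seed)
        events = rng.normal(mu, sd, size=area)
        counts = np.bincount(
            np.clip(events.astype(int), 0, n_channels - 1),
            minlength=n_channels,
        )
        return FcmHistogram(counts)

    def test_center_matches_mode_for_symmetric_peak(self):
        hist = self._gauss_hist()
        p = fit_peak(hist, (170, 230))
        mode = int(np.argmax(hist.channel_counts))
        assert abs(p.position - (mode + 0.5)) < 2.0
        assert p.position == pytest.approx(200.0, abs=0.6)

    def test_cv_recovered_within_10_percent(self):
        # one tube at n=5000: fitted CV of the sample 2C peak vs nominal
        p = SimulationParams(
            two_c_pg=15.7, p_pg=3.55, standard=PISUM, cv=0.03, seed=21
        )
        hist = bin_events(simulate_sample(p))
        pos = 15.7 / p.gain_pg_per_channel
        fit = fit_peak(hist, (int(pos * 0.91), int(pos * 1.09)))
        assert fit.cv == pytest.approx(0.03, rel=0.10)

    def test_area_is_gaussian_integral(self):
        hist = self._gauss_hist(area=3000)
        p = fit_peak(hist, (170, 230))
        assert p.area == pytest.approx(3000, rel=0.05)

    def test_too_few_nonzero_channels(self):
        counts = np.zeros(1024, dtype=int)
        counts[100] = 50
        counts[101] = 60
        with pytest.raises(FitError):
            fit_peak(FcmHistogram(counts), (90, 110))


class TestDetection:
    def test_all_zero_histogram_errors(self):
        with pytest.raises(NoPeaksError):
            detect_peaks(FcmHistogram(np.zeros(1024, dtype=int)))

    def test_two_well_separated_gaussians(self):
        rng = np.random.default_rng(1)
        ev = np.concatenate(
            [rng.normal(200, 6, 3000), rng.normal(500, 15, 3000)]
        )
        hist = bin_events(EventTable(np.clip(ev, 0, None)))
        peaks = detect_peaks(hist)
        assert len(peaks) == 2
        assert peaks[0].position == pytest.approx(200, abs=0.5)
        assert peaks[1].position == pytest.approx(500, abs=1.0)

    def test_noiseless_recovers_k_plus_two_peaks(self):
        # nearly noise-free shapes: every nominal component appears, and
        # fitted positions match the 2C + k*P progression to < 0.1%
        p = SimulationParams(
            two_c_pg=15.7, p_pg=3.55, standard=PISUM, cv=0.005,
            debris_fraction=0.0, n_events=20000, seed=2,
        )
        hist = bin_events(simulate_sample(p))
        peaks = detect_peaks(hist, min_peak_events=50)
        assert len(peaks) == p.k_max + 2
        nominal = [8.76] + [15.7 + k * 3.55 for k in range(4)]
        nominal_ch = np.array(sorted(nominal)) / p.gain_pg_per_channel
        got = np.array([q.position for q in peaks])
        np.testing.assert_allclose(got, nominal_ch, rtol=1e-3)

    def test_full_series_recovered_for_large_genome_tube(self):
        # standard + four-peak endocycle series, all five recovered
        p = SimulationParams(
            two_c_pg=28.65, p_pg=3.59, standard=PISUM, cv=0.03, seed=4
        )
        peaks = detect_peaks(bin_events(simulate_sample(p)))
        assert len(peaks) == 5

    def test_detection_idempotent(self, ustulata_events):
        hist = bin_events(ustulata_events)
        a = detect_peaks(hist)
        b = detect_peaks(hist)
        assert [(p.position, p.sd, p.area) for p in a] == [
            (p.position, p.sd, p.area) for p in b
        ]

    def test_scale_equivariance_of_channel_positions(self):
        p = SimulationParams(two_c_pg=15.7, p_pg=3.55, standard=PISUM, seed=9)
        t = simulate_sample(p)
        h1 = bin_events(t, gain=1.0)
        h2 = bin_events(t, gain=1.5)
        p1 = detect_peaks(h1)
        p2 = detect_peaks(h2)
        assert len(p1) == len(p2)
        for a, b in zip(p1, p2):
            assert b.position == pytest.approx(a.position / 1.5, rel=5e-3)

    def test_quality_gates_drop_small_peaks(self):
        rng = np.random.default_rng(3)
        ev = np.concatenate(
            [rng.normal(200, 6, 3000), rng.normal(500, 15, 60)]
        )
        hist = bin_events(EventTable(np.clip(ev, 0, None)))
        det = GaussianPeakDetector(min_peak_events=100)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            det.fit(hist)
        assert len(det.peaks_) == 1
        assert any("min_peak_events" in r for r, _ in det.dropped_)

    def test_sklearn_param_interface(self):
        det = GaussianPeakDetector(min_peak_events=42)
        assert det.get_params()["min_peak_events"] == 42
        det.set_params(cv_max=0.2)
        assert det.cv_max == 0.2
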