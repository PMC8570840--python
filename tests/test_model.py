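"""Role assignment, genome-size and P estimation, the per-tube estimator."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from peflow import (
    EndoreplicationEstimator,
    PISUM,
    SOLANUM,
    SimulationParams,
    assign_peaks,
    calibrate_secondary_standard,
    estimate_P,
    estimate_genome_size,
    percent_P,
    simulate_sample,
)
from peflow.errors import (
    AssignmentError,
    InsufficientPeaksError,
    ModelViolationError,
    OverlapError,
    ParameterError,
)
from peflow.peaks import PeakFit


def _peak(pos, sd=None, area=1000.0, **kw):
    sd = sd if sd is not None else 0.03 * pos
    return PeakFit(position=pos, sd=sd, cv=sd / pos, area=area, **kw)


def _sample_peak(k, pos_pg, area=1000.0):
    return PeakFit(
        position=pos_pg * 20, sd=0.6 * k + 1, cv=0.03, area=area,
        role="sample", k=k, position_pg=pos_pg,
    )


class TestAssignPeaks:
    def test_series_with_primary_standard(self):
        # channel positions proportional to pg: standard + 4-peak series
        pgs = [8.76, 10.46, 13.99, 17.52, 21.05]
        peaks = [_peak(v * 11.0) for v in pgs]
        out = assign_peaks(peaks, PISUM)
        roles = [(p.role, p.k) for p in out]
        assert roles == [
            ("standard", None), ("sample", 0), ("sample", 1),
            ("sample", 2), ("sample", 3),
        ]
        assert out[1].position_pg == pytest.approx(10.46, rel=1e-9)

    def test_series_with_secondary_standard(self):
        peaks = [_peak(v * 30.0) for v in (2.57, 7.12, 10.01)]
        out = assign_peaks(peaks, SOLANUM)
        assert [p.role for p in out] == ["standard", "sample", "sample"]
        p_est = out[2].position_pg - out[1].position_pg
        assert p_est == pytest.approx(2.89, rel=1e-9)

    def test_identical_positions_overlap_error(self):
        peaks = [_peak(100.0), _peak(100.0)]
        with pytest.raises(OverlapError):
            assign_peaks(peaks, PISUM)

    def test_broken_progression_rejected(self):
        # no single-peak removal leaves an arithmetic progression within 2%
        peaks = [_peak(v) for v in (100.0, 210.0, 290.0, 430.0)]
        with pytest.raises(AssignmentError):
            assign_peaks(peaks, PISUM)

    def test_hint_restricts_standard_choice(self):
        pgs = [8.76, 10.46, 13.99, 17.52, 21.05]
        peaks = [_peak(v * 11.0) for v in pgs]
        out = assign_peaks(peaks, PISUM, hint=(9.0, 12.0))
        assert out[0].role == "standard"
        with pytest.raises(AssignmentError):
            assign_peaks(peaks, PISUM, hint=(50.0, 60.0))

    def test_fewer_than_two_peaks(self):
        with pytest.raises(AssignmentError):
            assign_peaks([_peak(100.0)], PISUM)


class TestGenomeSize:
    def test_ratio_one(self):
        assert estimate_genome_size(_peak(100.0), _peak(100.0), PISUM) == 8.76

    def test_ratio_two(self):
        assert estimate_genome_size(_peak(200.0), _peak(100.0), PISUM) == (
            pytest.approx(17.52)
        )

    def test_secondary_standard_path(self):
        # ratio chosen so the estimate lands on 7.12 pg
        ratio = 7.12 / 2.57
        est = estimate_genome_size(_peak(100.0 * ratio), _peak(100.0), SOLANUM)
        assert est == pytest.approx(7.12, rel=1e-9)


class TestEstimateP:
    def test_exact_progression(self):
        peaks = [_sample_peak(k, 10.0 + 3.0 * k) for k in range(4)]
        p, intercept = estimate_P(peaks)
        assert p == pytest.approx(3.0, abs=1e-12)
        assert intercept == pytest.approx(10.0, abs=1e-12)

    def test_three_peak_series(self):
        peaks = [
            _sample_peak(k, v) for k, v in enumerate([19.46, 26.52, 33.58])
        ]
        p, _ = estimate_P(peaks)
        assert p == pytest.approx(7.06, rel=1e-9)

    def test_two_peak_reduction_is_exact_difference(self):
        peaks = [_sample_peak(0, 11.7, area=900), _sample_peak(1, 15.1, area=300)]
        p, intercept = estimate_P(peaks)
        assert p == pytest.approx(15.1 - 11.7, abs=1e-12)
        assert intercept == pytest.approx(11.7, abs=1e-12)

    def test_single_peak_insufficient(self):
        with pytest.raises(InsufficientPeaksError):
            estimate_P([_sample_peak(0, 10.0)])

    def test_negative_slope_is_model_violation(self):
        peaks = [_sample_peak(0, 20.0), _sample_peak(1, 15.0)]
        with pytest.raises(ModelViolationError):
            estimate_P(peaks)

    def test_first_two_mode_ignores_higher_peaks(self):
        peaks = [
            _sample_peak(0, 10.0),
            _sample_peak(1, 13.0),
            _sample_peak(2, 17.5),  # off-progression
        ]
        p, _ = estimate_P(peaks, p_mode="first_two")
        assert p == pytest.approx(3.0, abs=1e-12)

    @given(
        st.lists(
            st.tuples(
                st.floats(min_value=0.1, max_value=50.0),
                st.floats(min_value=1.0, max_value=5000.0),
            ),
            min_size=2,
            max_size=6,
        ),
        st.floats(min_value=5.0, max_value=40.0),
        st.floats(min_value=0.5, max_value=8.0),
    )
    def test_regression_matches_normal_equations(self, noise_w, b0, slope):
        """Oracle: WLS slope/intercept from explicit normal equations."""
        peaks = []
        for k, (eps, w) in enumerate(noise_w):
            y = b0 + slope * k + eps * 0.01
            peaks.append(_sample_peak(k, y, area=w))
        p, intercept = estimate_P(peaks)
        # brute-force normal equations: (X^T W X) beta = X^T W y
        kk = np.arange(len(peaks), dtype=float)
        y = np.array([q.position_pg for q in peaks])
        w = np.array([q.area for q in peaks])
        xtwx = np.array(
            [[w.sum(), (w * kk).sum()], [(w * kk).sum(), (w * kk * kk).sum()]]
        )
        xtwy = np.array([(w * y).sum(), (w * kk * y).sum()])
        beta = np.linalg.solve(xtwx, xtwy)
        assert intercept == pytest.approx(beta[0], rel=1e-10, abs=1e-10)
        assert p == pytest.approx(beta[1], rel=1e-10, abs=1e-10)


class TestPercentP:
    @pytest.mark.parametrize(
        "p,two_c,expected",
        [(7.06, 19.46, 36.3), (2.89, 7.12, 40.6), (5.0, 10.0, 50.0)],
    )
    def test_published_pairs(self, p, two_c, expected):
        assert round(percent_P(p, two_c), 1) == expected

    def test_precondition(self):
        with pytest.raises(ParameterError):
            percent_P(11.0, 10.0)


class TestSecondaryCalibration:
    def test_identity_ratio(self):
        s = calibrate_secondary_standard([1.0], PISUM)
        assert s.two_c_pg == pytest.approx(8.76)
        assert s.role == "secondary"

    def test_solanum_ratio(self):
        r = 2.57 / 8.76
        s = calibrate_secondary_standard([r, r], PISUM, name="Solanum")
        assert round(s.two_c_pg, 2) == 2.57

    def test_mean_and_sd_recorded(self):
        s = calibrate_secondary_standard([0.5, 1.5], PISUM)
        assert s.two_c_pg == pytest.approx(8.76)
        assert "sd" in s.provenance and "n = 2" in s.provenance

    def test_empty_errors(self):
        with pytest.raises(ParameterError):
            calibrate_secondary_standard([], PISUM)


class TestEndoreplicationEstimator:
    def test_end_to_end_recovery(self, ustulata_events):
        est = EndoreplicationEstimator(standard=SOLANUM).fit(ustulata_events)
        assert est.two_c_pg_ == pytest.approx(10.46, rel=0.02)
        assert est.p_pg_ == pytest.approx(3.53, rel=0.02)
        assert est.p_percent_ == pytest.approx(33.7, abs=1.0)

    def test_intercept_consistent_with_2c(self, ustulata_events):
        est = EndoreplicationEstimator(standard=SOLANUM).fit(ustulata_events)
        assert abs(est.intercept_pg_ - est.two_c_pg_) / est.two_c_pg_ < 0.01

    def test_measurement_export(self, ustulata_events):
        est = EndoreplicationEstimator(standard=SOLANUM).fit(ustulata_events)
        m = est.to_measurement("tube-1")
        assert m.sample_id == "tube-1"
        assert m.p_percent == pytest.approx(
            100 * m.p_pg / m.two_c_pg, rel=1e-12
        )

    def test_pg_results_invariant_to_gain(self):
        p = SimulationParams(two_c_pg=15.7, p_pg=3.55, standard=PISUM, seed=9)
        t = simulate_sample(p)
        a = EndoreplicationEstimator(standard=PISUM, gain=1.0).fit(t)
        b = EndoreplicationEstimator(standard=PISUM, gain=1.5).fit(t)
        assert b.two_c_pg_ == pytest.approx(a.two_c_pg_, rel=5e-3)
        assert b.p_pg_ == pytest.approx(a.p_pg_, rel=1e-2)

    def test_overlapping_standard_raises(self):
        # sample 2C close enough to the standard that the two peaks are
        # resolvable but overlap within 2*(sd1+sd2): advise a secondary
        p = SimulationParams(
            two_c_pg=9.6, p_pg=3.2, standard=PISUM, seed=0,
            debris_fraction=0.0, n_events=20000,
        )
        t = simulate_sample(p)
        with pytest.raises(AssignmentError):
            EndoreplicationEstimator(standard=PISUM).fit(t)
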