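"""Ploidy inference and joint (2C, P) classification."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from peflow import (
    DelineationRule,
    PloidyClassifier,
    SampleMeasurement,
    diploid_P_band,
    infer_ploidy,
    joint_classify,
)
from peflow.errors import EmptySetError, LabelingError, ParameterError
from peflow.reference import REFERENCE_TABLE


def _rule(ref=3.55, **kw):
    return DelineationRule(p_diploid_ref=ref, **kw)


def _m(sid, two_c, p, taxon="t"):
    return SampleMeasurement(
        sample_id=sid, two_c_pg=two_c, p_pg=p,
        p_percent=100 * p / two_c, k_used=4, intercept_pg=two_c, taxon=taxon,
    )


class TestInferPloidy:
    def test_identity_is_diploid(self):
        ploidy, residual, ambiguous = infer_ploidy(3.55, _rule())
        assert (ploidy, residual, ambiguous) == (2, 0.0, False)

    def test_triploid_fold(self):
        # 5.27 pg vs a 3.55 pg diploid baseline: a 1.5-fold increase
        assert round(5.27 / 3.55, 1) == 1.5
        ploidy, residual, _ = infer_ploidy(5.27, _rule())
        assert ploidy == 3
        assert residual < 0.02

    def test_tetraploid_fold(self):
        # 7.06 pg is a twofold increase over the diploid baseline
        assert round(7.06 / 3.55) == 2
        ploidy, _, _ = infer_ploidy(7.06, _rule())
        assert ploidy == 4

    def test_large_residual_flags_ambiguous(self):
        _, residual, ambiguous = infer_ploidy(3.55 * 1.22, _rule())
        assert ambiguous and residual > 0.10

    @given(
        st.floats(min_value=0.5, max_value=20.0),
        st.floats(min_value=0.5, max_value=20.0),
        st.floats(min_value=0.01, max_value=100.0),
    )
    def test_monotone_and_scale_invariant(self, p_obs, ref, scale):
        """Ploidy is monotone in P and invariant to joint rescaling."""
        r = _rule(ref)
        ploidy, residual, amb = infer_ploidy(p_obs, r)
        ploidy_up, _, _ = infer_ploidy(p_obs * 1.6, r)
        assert ploidy_up >= ploidy
        scaled = infer_ploidy(p_obs * scale, _rule(ref * scale))
        assert scaled[0] == ploidy
        assert scaled[1] == pytest.approx(residual, rel=1e-9, abs=1e-9)


class TestPloidyClassifier:
    def test_bootstrap_reference_from_mixed_cohort(self, rng):
        p = np.concatenate(
            [
                rng.normal(3.55, 0.15, 100),  # diploids dominate
                rng.normal(5.27, 0.15, 4),
                rng.normal(7.06, 0.1, 6),
            ]
        )
        clf = PloidyClassifier().fit(p)
        assert clf.p_diploid_ref_ == pytest.approx(3.55, abs=0.1)
        pred = clf.predict([3.5, 5.3, 7.1])
        assert list(pred) == [2, 3, 4]

    def test_explicit_reference_wins(self):
        clf = PloidyClassifier(p_diploid_ref=4.0).fit([1.0, 2.0])
        assert clf.p_diploid_ref_ == 4.0

    def test_rejects_nonpositive(self):
        with pytest.raises(ParameterError):
            PloidyClassifier().fit([3.0, -1.0])


class TestJointClassify:
    def _taxon(self, n=5, two_c=28.1, p=3.55, taxon="A", start=0):
        return [
            _m(f"{taxon}-{start + i}", two_c, p, taxon=taxon) for i in range(n)
        ]

    def test_consistent_individuals(self):
        out = joint_classify(self._taxon(), rule=_rule())
        assert all(m.classification == "consistent" for m in out)
        assert all(m.deviation_loo_pct == pytest.approx(0.0) for m in out)

    def test_homoploid_divergent_with_published_deviation(self):
        # one individual at 23.8 pg in a taxon centred at 28.1 pg, same P:
        # deviation (28.1 - 23.8)/23.8 rounds to 18%
        ms = self._taxon(n=6) + [_m("A-out", 23.8, 3.55, taxon="A")]
        out = joint_classify(ms, rule=_rule())
        outlier = next(m for m in out if m.sample_id == "A-out")
        assert outlier.classification == "homoploid-divergent"
        assert round(outlier.deviation_pct) == 18

    def test_ploidy_variant_by_fold_change(self):
        ms = self._taxon(n=6) + [
            _m("A-3x", 28.1 * 1.5, 3.55 * 1.5, taxon="A")
        ]
        out = joint_classify(ms, rule=_rule())
        variant = next(m for m in out if m.sample_id == "A-3x")
        assert variant.classification == "ploidy-variant"
        assert variant.ploidy == 3

    def test_hybrid_suspect_when_intermediate_toward_other_taxon(self):
        ms = (
            self._taxon(n=6, two_c=28.1, taxon="A")
            + self._taxon(n=6, two_c=15.0, taxon="B")
            + [_m("A-hyb", 23.8, 3.55, taxon="A")]
        )
        out = joint_classify(ms, rule=_rule())
        hyb = next(m for m in out if m.sample_id == "A-hyb")
        assert hyb.classification == "homoploid-divergent"
        assert "hybrid-suspect" in hyb.flags

    def test_leave_one_out_mean_excludes_the_outlier(self):
        # toy 3-element set: the outlier's own value must not dilute the
        # reference it is compared against
        ms = [
            _m("a", 10.0, 3.5),
            _m("b", 10.0, 3.5),
            _m("c", 13.0, 3.5),
        ]
        out = joint_classify(ms, rule=_rule(3.5))
        c = next(m for m in out if m.sample_id == "c")
        assert c.deviation_loo_pct == pytest.approx(100 * 3.0 / 10.0)
        a = next(m for m in out if m.sample_id == "a")
        assert a.deviation_loo_pct == pytest.approx(100 * 1.5 / 11.5)

    def test_unlabeled_measurement_errors(self):
        bad = SampleMeasurement(
            sample_id="x", two_c_pg=10.0, p_pg=3.0, p_percent=30.0,
            k_used=2, intercept_pg=10.0,
        )
        with pytest.raises(LabelingError):
            joint_classify([bad, bad], rule=_rule())

    def test_singleton_taxon_errors(self):
        with pytest.raises(LabelingError):
            joint_classify(self._taxon(n=1), rule=_rule())


class TestDiploidPBand:
    def test_published_diploid_band_under_4_pg(self):
        rule = _rule()
        ms = [
            _m(f"r{i}", r.gs_mean, r.p_mean, taxon=r.taxon)
            for i, r in enumerate(REFERENCE_TABLE)
            if r.ploidy == 2
        ]
        lo, hi, ok = diploid_P_band(ms, rule)
        assert hi == 3.69
        assert lo == 2.89
        assert ok

    def test_single_diploid(self):
        lo, hi, ok = diploid_P_band([_m("a", 10.0, 3.0)], _rule(3.0))
        assert (lo, hi, ok) == (3.0, 3.0, True)

    def test_no_diploids_errors(self):
        tetra = _m("t", 20.0, 7.1)
        with pytest.raises(EmptySetError):
            diploid_P_band([tetra], _rule())
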