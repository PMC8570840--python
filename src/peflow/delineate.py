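"""Joint (2C, P) delineation: ploidy, cryptic homoploid lineages, hybrids.

The size of the endoreplicated part P scales with ploidy — a triploid
carries 1.5x and a tetraploid 2x the diploid P — while homoploid lineages
shift in 2C at essentially constant P.  Plotting 2C against P therefore
separates ploidy variation (P moves in integer folds) from cryptic
homoploid divergence (2C moves, P does not), and individuals whose 2C sits
between two taxa at unchanged P are hybrid suspects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator

from .errors import EmptySetError, LabelingError, ParameterError
from .model import SampleMeasurement

__all__ = [
    "DelineationRule",
    "infer_ploidy",
    "PloidyClassifier",
    "joint_classify",
    "diploid_P_band",
]


@dataclass
class DelineationRule:
    """Thresholds for the joint (2C, P) marker.

    ``p_diploid_ref`` is the reference diploid P (pg); ploidy is the nearest
    integer fold of it.  ``p_tol`` bounds "same P" (relative), and a 2C
    deviating by more than ``gs_hybrid_dev`` (relative) at constant P flags
    homoploid divergence.  Both thresholds are heuristics, not biology.
    """

    p_diploid_ref: float
    base_ploidy: int = 2
    p_tol: float = 0.10
    gs_hybrid_dev: float = 0.15
    diploid_p_bound: float = 4.0

    def __post_init__(self) -> None:
        if self.p_diploid_ref <= 0:
            raise ParameterError("p_diploid_ref must be > 0")
        if not 0 < self.p_tol < 0.5:
            raise ParameterError("p_tol must lie in (0, 0.5)")
        if not 0 < self.gs_hybrid_dev < 1:
            raise ParameterError("gs_hybrid_dev must lie in (0, 1)")
        if self.base_ploidy < 1:
            raise ParameterError("base_ploidy must be >= 1")


def infer_ploidy(p_obs: float, rule: DelineationRule) -> Tuple[int, float, bool]:
    """Infer ploidy from an observed P by nearest integer fold.

    Returns ``(ploidy, residual, ambiguous)``: ploidy is
    ``round(base_ploidy * p_obs / p_diploid_ref)`` (at least 1), residual
    the relative deviation of ``p_obs`` from that integer-fold value, and
    ``ambiguous`` is set when the residual exceeds ``p_tol``.
    """
    if p_obs <= 0:
        raise ParameterError("p_obs must be > 0")
    raw = rule.base_ploidy * p_obs / rule.p_diploid_ref
    ploidy = max(1, int(round(raw)))
    fold_value = ploidy * rule.p_diploid_ref / rule.base_ploidy
    residual = abs(p_obs - fold_value) / fold_value
    return ploidy, residual, residual > rule.p_tol


class PloidyClassifier(BaseEstimator):
    """Nearest-integer-fold ploidy classifier over P values.

    When ``p_diploid_ref`` is not given, ``fit`` bootstraps it from the data:
    start from the median P (valid when diploids dominate, as in mixed field
    cohorts), classify, and re-take the median over the inferred diploids.

    Attributes
    ----------
    p_diploid_ref_ : the reference diploid P actually used (pg).
    """

    def __init__(
        self,
        p_diploid_ref: Optional[float] = None,
        base_ploidy: int = 2,
        p_tol: float = 0.10,
    ) -> None:
        self.p_diploid_ref = p_diploid_ref
        self.base_ploidy = base_ploidy
        self.p_tol = p_tol

    def _rule(self, ref: float) -> DelineationRule:
        return DelineationRule(
            p_diploid_ref=ref, base_ploidy=self.base_ploidy, p_tol=self.p_tol
        )

    def fit(self, p_values: Sequence[float], y=None) -> "PloidyClassifier":
        p = np.asarray(p_values, dtype=float)
        if p.size == 0:
            raise ParameterError("no P values to fit")
        if (p <= 0).any():
            raise ParameterError("P values must be > 0")
        if self.p_diploid_ref is not None:
            self.p_diploid_ref_ = float(self.p_diploid_ref)
            return self
        ref = float(np.median(p))
        for _ in range(2):
            rule = self._rule(ref)
            ploidies = np.array([infer_ploidy(v, rule)[0] for v in p])
            diploid = p[ploidies == self.base_ploidy]
            if diploid.size == 0:
                break
            ref = float(np.median(diploid))
        self.p_diploid_ref_ = ref
        return self

    def predict(self, p_values: Sequence[float]) -> np.ndarray:
        rule = self._rule(self.p_diploid_ref_)
        return np.array(
            [infer_ploidy(float(v), rule)[0] for v in np.asarray(p_values)],
            dtype=int,
        )

    def residuals(self, p_values: Sequence[float]) -> np.ndarray:
        rule = self._rule(self.p_diploid_ref_)
        return np.array(
            [infer_ploidy(float(v), rule)[1] for v in np.asarray(p_values)]
        )


def joint_classify(
    measurements: Sequence[SampleMeasurement],
    rule: Optional[DelineationRule] = None,
) -> List[SampleMeasurement]:
    """Label each measurement consistent / ploidy-variant / homoploid-divergent.

    Statistics are computed against the *leave-one-out* taxon mean so an
    outlier cannot mask itself.  An individual is

    * ``ploidy-variant`` when its inferred ploidy differs from the taxon's
      majority ploidy,
    * ``homoploid-divergent`` when P stays within ``p_tol`` of the taxon
      mean but 2C deviates by more than ``gs_hybrid_dev`` — the cryptic
      homoploid-lineage signal; such individuals additionally get a
      ``hybrid-suspect`` flag when their 2C is intermediate toward another
      taxon's mean,
    * ``consistent`` otherwise.

    Two deviation percentages are recorded: ``deviation_pct`` uses the
    individual's own 2C as denominator (the convention behind "deviating by
    ~18%"), ``deviation_loo_pct`` the leave-one-out mean (the flagging
    statistic).
    """
    ms = list(measurements)
    if any(m.taxon is None for m in ms):
        raise LabelingError("every measurement needs a taxon label")
    by_taxon: Dict[str, List[int]] = {}
    for i, m in enumerate(ms):
        by_taxon.setdefault(m.taxon, []).append(i)
    for taxon, idxs in by_taxon.items():
        if len(idxs) < 2:
            raise LabelingError(
                f"taxon {taxon!r} has fewer than 2 measurements; "
                "deviation statistics are undefined"
            )

    if rule is None:
        clf = PloidyClassifier().fit([m.p_pg for m in ms])
        rule = DelineationRule(p_diploid_ref=clf.p_diploid_ref_)

    taxon_gs_mean = {
        t: float(np.mean([ms[i].two_c_pg for i in idx]))
        for t, idx in by_taxon.items()
    }
    out: List[SampleMeasurement] = []
    for taxon, idxs in by_taxon.items():
        gs = np.array([ms[i].two_c_pg for i in idxs])
        pp = np.array([ms[i].p_pg for i in idxs])
        ploidies = [infer_ploidy(v, rule)[0] for v in pp]
        majority = int(np.bincount(ploidies).argmax())
        n = len(idxs)
        for j, i in enumerate(idxs):
            m = ms[i]
            loo_gs = float((gs.sum() - gs[j]) / (n - 1))
            loo_p = float((pp.sum() - pp[j]) / (n - 1))
            ploidy, resid, ambiguous = infer_ploidy(m.p_pg, rule)
            dev_self = 100.0 * abs(loo_gs - m.two_c_pg) / m.two_c_pg
            dev_loo = 100.0 * abs(m.two_c_pg - loo_gs) / loo_gs
            p_same = abs(m.p_pg - loo_p) / loo_p <= rule.p_tol
            flags = set(m.flags)
            if ambiguous:
                flags.add("ambiguous-ploidy")
            if ploidy != majority:
                cls = "ploidy-variant"
            elif p_same and dev_loo / 100.0 > rule.gs_hybrid_dev:
                cls = "homoploid-divergent"
                for other, other_mean in taxon_gs_mean.items():
                    if other == taxon:
                        continue
                    lo, hi = sorted((loo_gs, other_mean))
                    if lo < m.two_c_pg < hi:
                        flags.add("hybrid-suspect")
                        break
            else:
                cls = "consistent"
            out.append(
                SampleMeasurement(
                    sample_id=m.sample_id,
                    two_c_pg=m.two_c_pg,
                    p_pg=m.p_pg,
                    p_percent=m.p_percent,
                    k_used=m.k_used,
                    intercept_pg=m.intercept_pg,
                    ploidy=ploidy,
                    taxon=m.taxon,
                    flags=flags,
                    classification=cls,
                    deviation_pct=dev_self,
                    deviation_loo_pct=dev_loo,
                )
            )
    return out


def diploid_P_band(
    measurements: Sequence[SampleMeasurement],
    rule: DelineationRule,
) -> Tuple[float, float, bool]:
    """Range of P over inferred diploids and whether it stays under the bound.

    Diploid taxa share similar P regardless of overall genome size; the
    default bound is 4 pg.  Returns ``(min, max, max < bound)``.
    """
    ps = []
    for m in measurements:
        ploidy = (
            m.ploidy
            if m.ploidy is not None
            else infer_ploidy(m.p_pg, rule)[0]
        )
        if ploidy == rule.base_ploidy:
            ps.append(m.p_pg)
    if not ps:
        raise EmptySetError("no diploid measurements")
    return min(ps), max(ps), max(ps) < rule.diploid_p_bound
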