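"""Genome-size and partial-endoreplication estimation.

Partial endoreplication produces a fluorescence peak series at ``2C + k*P``
for endocycle index k = 0..K: only a fixed part P of the genome replicates
per endocycle, so consecutive peaks are an *arithmetic*, not geometric,
progression.  Against an internal standard of known 2C this module

* assigns detected peaks to roles (standard vs. sample k = 0..K),
* estimates the 2C genome size from the sample/standard position ratio,
* estimates P as the slope of a weighted regression of peak position (pg)
  on k — which reduces exactly to the classical second-minus-first peak
  difference when only two sample peaks exist, and
* derives P% = 100*P/2C, the endoreplicated fraction of the genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator

from .errors import (
    AssignmentError,
    InsufficientPeaksError,
    ModelViolationError,
    OverlapError,
    ParameterError,
)
from .io import EventTable, FcmHistogram, PISUM, StandardDef, bin_events
from .peaks import GaussianPeakDetector, PeakFit

__all__ = [
    "SampleMeasurement",
    "assign_peaks",
    "estimate_genome_size",
    "estimate_P",
    "percent_P",
    "calibrate_secondary_standard",
    "EndoreplicationEstimator",
]


@dataclass
class SampleMeasurement:
    """Derived quantities for one individual."""

    sample_id: str
    two_c_pg: float
    p_pg: float
    p_percent: float
    k_used: int
    intercept_pg: float
    ploidy: Optional[int] = None
    taxon: Optional[str] = None
    flags: set = field(default_factory=set)
    classification: Optional[str] = None
    deviation_pct: Optional[float] = None
    deviation_loo_pct: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 < self.p_pg < self.two_c_pg):
            raise ParameterError("requires 0 < P < 2C")
        if not (0 < self.p_percent < 100):
            raise ParameterError("P% must lie in (0, 100)")


# ---------------------------------------------------------------------------
# role assignment


def _progression_residual(positions: np.ndarray) -> float:
    """Max relative residual of positions against the best-fit line in k."""
    m = positions.size
    if m < 2:
        return 0.0
    k = np.arange(m, dtype=float)
    design = np.column_stack([np.ones(m), k])
    coef, *_ = np.linalg.lstsq(design, positions, rcond=None)
    fitted = design @ coef
    return float(np.max(np.abs(positions - fitted) / positions))


def assign_peaks(
    peaks: Sequence[PeakFit],
    standard: StandardDef,
    hint: Optional[Tuple[float, float]] = None,
    progression_tol: float = 0.02,
) -> List[PeakFit]:
    """Assign standard / sample-k roles to detected peaks.

    The standard peak is the one whose removal leaves the remaining peaks
    closest to an arithmetic progression ``2C + k*P``; when ``hint`` (an
    expected sample-2C range in pg) is given, only candidates whose implied
    2C falls inside it are considered.  Remaining peaks get k = 0..K by
    ascending position and all positions are converted to pg through the
    standard.  A standard peak overlapping the sample 2C peak (centers
    closer than twice the summed spreads) raises :class:`OverlapError`
    advising a secondary standard.
    """
    peaks = sorted(peaks, key=lambda p: p.position)
    if len(peaks) < 2:
        raise AssignmentError("role assignment requires at least 2 peaks")

    positions = np.array([p.position for p in peaks])
    areas = np.array([p.area for p in peaks])
    best: Optional[Tuple[bool, int, float, int]] = None
    for i in range(len(peaks)):
        rest = np.delete(positions, i)
        if hint is not None:
            implied_2c = rest[0] / positions[i] * standard.two_c_pg
            if not (hint[0] <= implied_2c <= hint[1]):
                continue
        score = _progression_residual(rest)
        # a real endocycle series steps by P < 2C; candidates implying
        # otherwise lose ties against physically plausible assignments
        implausible = bool(
            rest.size >= 2 and np.mean(np.diff(rest)) >= rest[0]
        )
        # endocycle populations shrink with k, so series areas decay;
        # count clear inversions to break ties between near-perfect
        # progressions (e.g. a standard sitting one P below the 2C peak)
        rest_areas = np.delete(areas, i)
        area_inversions = int(
            np.sum(rest_areas[1:] > 1.1 * rest_areas[:-1])
        )
        # scores within half a percent are indistinguishable given fit
        # noise; only then does the area pattern arbitrate
        key = (
            implausible,
            int(score / 0.005),
            area_inversions,
            round(score, 12),
            i,
        )
        if best is None or key < best:
            best = key
    if best is None:
        raise AssignmentError(
            "no candidate standard peak yields a sample 2C inside the hint range"
        )
    score, std_idx = best[3], best[4]
    if score >= progression_tol:
        raise AssignmentError(
            f"no peak subset fits an arithmetic progression within "
            f"{progression_tol:.1%} (best residual {score:.1%})"
        )

    std_peak = peaks[std_idx]
    sample_peaks = [p for j, p in enumerate(peaks) if j != std_idx]
    first = sample_peaks[0]
    if len(sample_peaks) >= 2:
        # physical plausibility: the series step P must stay below 2C
        step = np.mean(np.diff([p.position for p in sample_peaks]))
        if step >= first.position:
            raise AssignmentError(
                "peak spacing implies P >= 2C; the series cannot be a "
                "partial-endoreplication progression"
            )
    if abs(std_peak.position - first.position) < 2.0 * (std_peak.sd + first.sd):
        raise OverlapError(
            "standard and sample 2C peaks overlap (centers closer than "
            "2*(sd1+sd2)); re-measure against a secondary standard of a "
            "different genome size"
        )

    pg_per_channel = standard.two_c_pg / std_peak.position
    out: List[PeakFit] = []
    for j, p in enumerate(peaks):
        if j == std_idx:
            out.append(
                replace(
                    p,
                    role="standard",
                    k=None,
                    position_pg=standard.two_c_pg,
                    flags=set(p.flags),
                )
            )
        else:
            k = sample_peaks.index(p)
            out.append(
                replace(
                    p,
                    role="sample",
                    k=k,
                    position_pg=p.position * pg_per_channel,
                    flags=set(p.flags),
                )
            )
    return out


# ---------------------------------------------------------------------------
# the estimators behind Table-1 style numbers


def estimate_genome_size(
    sample_2c_peak: PeakFit, standard_peak: PeakFit, standard: StandardDef
) -> float:
    """2C (pg) = (sample 2C position / standard position) * standard 2C."""
    if sample_2c_peak.position <= 0 or standard_peak.position <= 0:
        raise ParameterError("peak positions must be > 0")
    return sample_2c_peak.position / standard_peak.position * standard.two_c_pg


def estimate_P(
    sample_peaks: Sequence[PeakFit], p_mode: str = "regression"
) -> Tuple[float, float]:
    """Estimate the endoreplicated-part size P (pg) from the peak series.

    ``regression`` fits an area-weighted least-squares line of position (pg)
    on endocycle index k; the slope is P, the intercept a 2C-consistency
    check.  ``first_two`` uses only the difference between the two lowest
    peaks (the classical two-peak ratio).  With exactly two peaks the modes
    coincide identically.
    """
    pk = sorted(
        (p for p in sample_peaks if p.role == "sample"), key=lambda p: p.k
    )
    ks = [p.k for p in pk]
    if len(set(ks)) < 2:
        raise InsufficientPeaksError(
            "P is undefined with fewer than two distinct sample peaks"
        )
    if any(p.position_pg is None for p in pk):
        raise ParameterError("sample peaks must carry pg positions")
    if p_mode == "first_two":
        pk = pk[:2]
    elif p_mode != "regression":
        raise ParameterError(f"unknown p_mode {p_mode!r}")

    if len(pk) == 2:
        # the weighted line through two points is their difference exactly
        dk = pk[1].k - pk[0].k
        slope = (pk[1].position_pg - pk[0].position_pg) / dk
        intercept = pk[0].position_pg - slope * pk[0].k
        if slope <= 0:
            raise ModelViolationError(
                f"fitted peak series has non-positive slope ({slope:.3g} pg)"
            )
        return slope, intercept

    k = np.array([p.k for p in pk], dtype=float)
    y = np.array([p.position_pg for p in pk], dtype=float)
    w = np.array([p.area for p in pk], dtype=float)
    sw = np.sqrt(w)
    design = np.column_stack([np.ones_like(k), k]) * sw[:, None]
    coef, *_ = np.linalg.lstsq(design, y * sw, rcond=None)
    intercept, slope = float(coef[0]), float(coef[1])
    if slope <= 0:
        raise ModelViolationError(
            f"fitted peak series has non-positive slope ({slope:.3g} pg); "
            "the 2C + k*P model is violated"
        )
    return slope, intercept


def percent_P(p_pg: float, two_c_pg: float) -> float:
    """P% = 100 * P / 2C, the endoreplicated fraction of the genome."""
    if not (0 < p_pg < two_c_pg):
        raise ParameterError("requires 0 < P < 2C")
    return 100.0 * p_pg / two_c_pg


def calibrate_secondary_standard(
    ratios: Sequence[float],
    primary: StandardDef,
    name: str = "secondary standard",
) -> StandardDef:
    """Calibrate a secondary standard from repeated co-runs with the primary.

    ``ratios`` are secondary/primary peak-position ratios from independent
    tubes; the secondary's 2C is their mean times the primary 2C, with n and
    sd recorded in the provenance note.
    """
    ratios = np.asarray(ratios, dtype=float)
    if ratios.size == 0:
        raise ParameterError("at least one ratio is required")
    if (ratios <= 0).any():
        raise ParameterError("ratios must be > 0")
    mean = float(ratios.mean())
    sd = float(ratios.std(ddof=1)) if ratios.size > 1 else 0.0
    return StandardDef(
        name,
        mean * primary.two_c_pg,
        role="secondary",
        provenance=(
            f"calibrated against {primary.name} (2C = {primary.two_c_pg} pg): "
            f"n = {ratios.size}, mean ratio = {mean:.6g}, sd = {sd:.3g}"
        ),
    )


# ---------------------------------------------------------------------------
# end-to-end per-sample estimator


class EndoreplicationEstimator(BaseEstimator):
    """Estimate 2C, P and P% of one tube from events or a histogram.

    Composes binning, :class:`~peflow.peaks.GaussianPeakDetector`, role
    assignment and the P regression into a single fit-shaped estimator.

    Parameters largely forward to the detector and assignment steps; see
    those for semantics.  ``standard`` defaults to Pisum sativum 'Ctirad'
    (2C = 8.76 pg).

    Attributes
    ----------
    peaks_ : assigned PeakFit list (standard + sample k = 0..K).
    two_c_pg_, p_pg_, p_percent_, intercept_pg_ : the derived quantities.
    k_used_ : number of sample peaks entering the P estimate.
    flags_ : quality flags ('merged-peaks', 'low-peak-count', ...).
    """

    def __init__(
        self,
        standard: Optional[StandardDef] = None,
        n_channels: int = 1024,
        gain: float = 1.0,
        smooth_window: int = 9,
        min_peak_events: int = 100,
        cv_max: float = 0.10,
        min_amplitude: float = 2.0,
        progression_tol: float = 0.02,
        p_mode: str = "regression",
        hint: Optional[Tuple[float, float]] = None,
    ) -> None:
        self.standard = standard
        self.n_channels = n_channels
        self.gain = gain
        self.smooth_window = smooth_window
        self.min_peak_events = min_peak_events
        self.cv_max = cv_max
        self.min_amplitude = min_amplitude
        self.progression_tol = progression_tol
        self.p_mode = p_mode
        self.hint = hint

    def fit(self, X, y=None) -> "EndoreplicationEstimator":
        if isinstance(X, EventTable):
            hist = bin_events(X, n_channels=self.n_channels, gain=self.gain)
        elif isinstance(X, FcmHistogram):
            hist = X
        else:
            raise ParameterError(
                "EndoreplicationEstimator.fit expects an EventTable or "
                "FcmHistogram"
            )
        standard = self.standard if self.standard is not None else PISUM
        detector = GaussianPeakDetector(
            smooth_window=self.smooth_window,
            min_peak_events=self.min_peak_events,
            cv_max=self.cv_max,
            min_amplitude=self.min_amplitude,
        )
        raw = detector.fit(hist).peaks_
        assigned = assign_peaks(
            raw, standard, hint=self.hint, progression_tol=self.progression_tol
        )
        sample_peaks = [p for p in assigned if p.role == "sample"]
        std_peak = next(p for p in assigned if p.role == "standard")

        self.peaks_ = assigned
        self.two_c_pg_ = estimate_genome_size(sample_peaks[0], std_peak, standard)
        p_pg, intercept = estimate_P(sample_peaks, p_mode=self.p_mode)
        self.p_pg_ = p_pg
        self.intercept_pg_ = intercept
        self.p_percent_ = percent_P(p_pg, self.two_c_pg_)
        self.k_used_ = len(sample_peaks) if self.p_mode == "regression" else 2
        self.flags_ = set()
        if any("merged" in p.flags for p in assigned):
            self.flags_.add("merged-peaks")
        if len(sample_peaks) == 2:
            self.flags_.add("low-peak-count")
        self.sample_meta_ = dict(hist.meta)
        return self

    def to_measurement(self, sample_id: Optional[str] = None) -> SampleMeasurement:
        if sample_id is None:
            sample_id = str(self.sample_meta_.get("sample_id", "sample"))
        return SampleMeasurement(
            sample_id=sample_id,
            two_c_pg=self.two_c_pg_,
            p_pg=self.p_pg_,
            p_percent=self.p_percent_,
            k_used=self.k_used_,
            intercept_pg=self.intercept_pg_,
            taxon=self.sample_meta_.get("taxon"),
            flags=set(self.flags_),
        )
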