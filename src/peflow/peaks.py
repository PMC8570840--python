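"""Peak detection and single-Gaussian fitting on 1D fluorescence histograms.

The detector works by iterative peak stripping: smooth the histogram with
a moving-window quadratic (Savitzky-Golay) filter, take the largest
remaining local maximum, refine it with a weighted least-squares Gaussian
fit on a window of +-3 preliminary standard deviations, subtract the
fitted component, and repeat until no maximum stands above the amplitude
floor.  A final refinement pass refits every retained peak against the raw
counts minus all *other* fitted components, which keeps centers honest
when endocycle peaks sit only a few standard deviations apart.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter
from sklearn.base import BaseEstimator

from .errors import EmptyGateError, FitError, NoPeaksError, ParameterError
from .io import EventTable, FcmHistogram

__all__ = [
    "PeakFit",
    "gate_events",
    "fit_peak",
    "detect_peaks",
    "GaussianPeakDetector",
]


@dataclass
class PeakFit:
    """One fitted histogram peak.

    ``position`` and ``sd`` are in channel units; ``position_pg`` is filled
    once the peak is assigned a role against the internal standard.
    """

    position: float
    sd: float
    cv: float
    area: float
    role: str = "unassigned"
    k: Optional[int] = None
    position_pg: Optional[float] = None
    flags: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise ParameterError("peak position must be > 0")
        if self.cv <= 0 or self.area <= 0:
            raise ParameterError("peak cv and area must be > 0")
        if (self.k is not None) != (self.role == "sample"):
            raise ParameterError("endocycle index k is set iff role == 'sample'")


def gate_events(
    events: EventTable,
    fl_range: Optional[Tuple[float, float]] = None,
    ssc_range: Optional[Tuple[float, float]] = None,
) -> EventTable:
    """Return the subset of events inside a rectangular gate.

    Ranges are half-open ``[lo, hi)`` ordered pairs; ``ssc_range`` requires
    side-scatter data.  The applied gate is recorded in the metadata.
    """
    mask = np.ones(len(events), dtype=bool)
    for name, rng in (("fl", fl_range), ("ssc", ssc_range)):
        if rng is None:
            continue
        lo, hi = rng
        if not lo < hi:
            raise ParameterError(f"{name}_range must be an ordered pair")
        if name == "ssc":
            if events.side_scatter is None:
                raise ParameterError("ssc_range given but no side-scatter data")
            vals = events.side_scatter
        else:
            vals = events.fluorescence
        mask &= (vals >= lo) & (vals < hi)
    if not mask.any():
        raise EmptyGateError("gate excludes all events")
    meta = dict(events.meta)
    meta["gate"] = {"fl": fl_range, "ssc": ssc_range}
    meta["n_events"] = int(mask.sum())
    ssc = events.side_scatter[mask] if events.side_scatter is not None else None
    return EventTable(events.fluorescence[mask], ssc, meta=meta)


def _gaussian(x, amp, mu, sd):
    return amp * np.exp(-0.5 * ((x - mu) / sd) ** 2)


def fit_peak(hist: FcmHistogram, window: Tuple[int, int]) -> PeakFit:
    """Weighted least-squares single-Gaussian fit on a channel window.

    ``window`` is an inclusive channel-index pair.  Counts are weighted by
    their Poisson uncertainty; the returned area is the Gaussian integral,
    not the raw window sum.
    """
    lo, hi = int(window[0]), int(window[1])
    lo = max(lo, 0)
    hi = min(hi, hist.n_channels - 1)
    if hi < lo:
        raise ParameterError("empty fit window")
    y = hist.channel_counts[lo : hi + 1].astype(float)
    x = hist.channel_centers[lo : hi + 1]
    if int((y > 0).sum()) < 5:
        raise FitError("fit window holds fewer than 5 nonzero channels")

    total = y.sum()
    mu0 = float((x * y).sum() / total)
    var0 = float(((x - mu0) ** 2 * y).sum() / total)
    sd0 = max(np.sqrt(var0), 0.5)
    amp0 = max(float(y.max()), 1.0)
    sigma_w = np.sqrt(np.maximum(y, 1.0))

    def _jac(xv, amp, mu, sd):
        z = (xv - mu) / sd
        e = np.exp(-0.5 * z**2)
        return np.column_stack([e, amp * e * z / sd, amp * e * z**2 / sd])

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _gaussian,
                x,
                y,
                p0=(amp0, mu0, sd0),
                sigma=sigma_w,
                jac=_jac,
                method="lm",
                maxfev=300,
            )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"Gaussian fit did not converge: {exc}") from exc
    amp, mu, sd = (float(v) for v in popt)
    sd = abs(sd)  # the Gaussian is even in sd; LM may converge to -sd
    if (
        not np.isfinite([amp, mu, sd]).all()
        or amp <= 0
        or sd <= 1e-6
        or mu <= 0
        or not (x[0] - sd <= mu <= x[-1] + sd)
    ):
        raise FitError("degenerate Gaussian fit")
    area = amp * sd * np.sqrt(2.0 * np.pi)
    return PeakFit(position=mu, sd=sd, cv=sd / mu, area=area)


class GaussianPeakDetector(BaseEstimator):
    """Detect and fit peaks in a binned fluorescence histogram.

    Parameters
    ----------
    smooth_window : odd int, default 9
        Width of the moving-window quadratic (Savitzky-Golay) smoother used
        only for candidate picking; fits run on the raw counts.
    min_peak_events : int, default 100
        Peaks whose fitted Gaussian area falls below this are discarded.
    cv_max : float, default 0.10
        Peaks with fitted CV above this quality gate are discarded.
    min_amplitude : float, default 2.0
        Amplitude floor (smoothed counts per channel) at which the
        stripping loop stops looking for further peaks.
    max_peaks : int, default 25
        Hard cap on stripping iterations.

    Attributes
    ----------
    peaks_ : list of PeakFit, sorted by position.
    dropped_ : list of (reason, channel) for candidates that were rejected.
    """

    def __init__(
        self,
        smooth_window: int = 9,
        min_peak_events: int = 100,
        cv_max: float = 0.10,
        min_amplitude: float = 2.0,
        max_peaks: int = 25,
    ) -> None:
        self.smooth_window = smooth_window
        self.min_peak_events = min_peak_events
        self.cv_max = cv_max
        self.min_amplitude = min_amplitude
        self.max_peaks = max_peaks

    # -- internals ----------------------------------------------------------

    def _smooth(self, counts: np.ndarray) -> np.ndarray:
        w = int(self.smooth_window)
        if w < 3 or w % 2 == 0:
            raise ParameterError("smooth_window must be odd and >= 3")
        if self.min_peak_events < 1:
            raise ParameterError("min_peak_events must be >= 1")
        return savgol_filter(counts.astype(float), w, 2)

    @staticmethod
    def _prelim_sd(counts: np.ndarray, ch: int) -> float:
        """Half-width-at-half-max spread estimate around a candidate.

        Uses twice the *smaller* of the two half-widths: an unresolved
        neighbour inflates one flank, while the cleaner flank still
        reflects the candidate's own width.
        """
        half = counts[ch] / 2.0
        left = ch
        while left > 0 and counts[left] > half:
            left -= 1
        right = ch
        n = len(counts)
        while right < n - 1 and counts[right] > half:
            right += 1
        fwhm = max(2 * min(ch - left, right - ch), 2)
        return fwhm / 2.3548  # FWHM of a Gaussian = 2.3548 sd

    def _strip(self, hist: FcmHistogram) -> List[PeakFit]:
        """Iteratively locate, fit and subtract the dominant remaining peak.

        The preliminary width of each candidate starts from the half-width
        at half-maximum of the smoothed residual; once peaks have been
        fitted, it is clamped toward the width expected under a shared
        coefficient of variation (sd proportional to position), which keeps
        candidate windows sane where the residual is noise-dominated.
        """
        residual = hist.channel_counts.astype(float)
        centers = hist.channel_centers
        masked = np.zeros(residual.size, dtype=bool)
        fits: List[PeakFit] = []
        for _ in range(int(self.max_peaks)):
            smoothed = self._smooth(np.maximum(residual, 0.0))
            avail = np.where(~masked, smoothed, -np.inf)
            ch = int(np.argmax(avail))  # ties keep the lower channel
            if avail[ch] < self.min_amplitude:
                break
            sd0 = self._prelim_sd(smoothed, ch)
            if fits:
                sd_exp = float(np.median([p.cv for p in fits])) * (ch + 0.5)
                sd0 = float(np.clip(sd0, 0.75 * sd_exp, 1.5 * sd_exp))
            # cheap triage: even a generous amplitude x width bound cannot
            # reach min_peak_events -> not worth a least-squares fit
            if avail[ch] * sd0 * np.sqrt(2.0 * np.pi) * 2.0 < self.min_peak_events:
                span = max(int(np.ceil(sd0 / 2.0)), 2)
                masked[max(ch - span, 0) : ch + span + 1] = True
                continue
            lo = int(np.floor(ch - 2.5 * sd0))
            hi = int(np.ceil(ch + 2.5 * sd0))
            sub = FcmHistogram(
                np.maximum(np.rint(residual), 0).astype(np.int64),
                gain=hist.gain,
            )

            def _reject(reason: str) -> None:
                self.dropped_.append((reason, ch))
                warnings.warn(
                    f"peak candidate at channel {ch} dropped: {reason}",
                    stacklevel=4,
                )
                span = max(int(np.ceil(sd0 / 2.0)), 2)
                masked[max(ch - span, 0) : ch + span + 1] = True

            try:
                p = fit_peak(sub, (lo, hi))
            except (FitError, ParameterError) as exc:
                _reject(f"fit-failed: {exc}")
                continue
            if p.sd > 2.5 * sd0:
                # absorbed an unresolved complex, not a single peak
                _reject(f"blob fit (sd {p.sd:.1f} >> expected {sd0:.1f})")
                continue
            amp = p.area / (p.sd * np.sqrt(2.0 * np.pi))
            residual = residual - _gaussian(centers, amp, p.position, p.sd)
            # a component is claimed once; do not re-pick its summit
            span = max(int(np.ceil(p.sd)), 2)
            c = int(p.position)
            masked[max(c - span, 0) : c + span + 1] = True
            fits.append(p)
        return fits

    def _joint_refit(
        self, hist: FcmHistogram, fits: List[PeakFit]
    ) -> List[PeakFit]:
        """Simultaneous least-squares refit of all retained components.

        Sequential stripping leaves first-order contamination between
        neighbouring peaks; refitting every Gaussian at once on the union
        of their supports removes it.  The refit shares a single relative
        width ``c`` across components (sd_i = c * mu_i): on a linear
        fluorescence axis every peak of a tube carries essentially the
        same coefficient of variation, and tying the widths keeps weak
        high-k components from drifting into their neighbours' tails.
        Falls back to the input fits when the joint fit fails.
        """
        if len(fits) < 2:
            return fits
        centers = hist.channel_centers
        y = hist.channel_counts.astype(float)
        mask = np.zeros(y.size, dtype=bool)
        for p in fits:
            mask |= np.abs(centers - p.position) < 4.0 * p.sd
        x, yv = centers[mask], y[mask]
        sigma_w = np.sqrt(np.maximum(yv, 1.0))
        n = len(fits)
        c0 = float(np.median([p.cv for p in fits]))
        p0 = np.concatenate(
            [[c0]]
            + [
                [p.area / (p.sd * np.sqrt(2 * np.pi)), p.position]
                for p in fits
            ]
        )

        def model(xv, c, *theta):
            th = np.asarray(theta).reshape(n, 2)
            return _gaussian(
                xv[:, None], th[:, 0], th[:, 1], np.abs(c) * th[:, 1]
            ).sum(axis=1)

        def jac(xv, c, *theta):
            c = abs(c)
            th = np.asarray(theta).reshape(n, 2)
            dc = np.zeros(xv.size)
            cols = []
            for amp, mu in th:
                sd = c * mu
                z = (xv - mu) / sd
                e = np.exp(-0.5 * z**2)
                dc += amp * e * z**2 / c
                cols += [e, amp * e * z * xv / (c * mu**2)]
            return np.column_stack([dc] + cols)

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    model, x, yv, p0=p0, sigma=sigma_w, jac=jac,
                    method="lm", maxfev=2000,
                )
        except (RuntimeError, ValueError):
            return fits
        c = abs(float(popt[0]))
        if not (1e-5 < c < 0.5):
            return fits
        out: List[PeakFit] = []
        for amp, mu in np.asarray(popt[1:]).reshape(n, 2):
            if np.isfinite([amp, mu]).all() and amp > 0 and mu > 0:
                sd = c * mu
                out.append(
                    PeakFit(
                        position=float(mu),
                        sd=float(sd),
                        cv=c,
                        area=float(amp * sd * np.sqrt(2 * np.pi)),
                    )
                )
        return out if out else fits

    def _strip_residual(
        self, hist: FcmHistogram, fits: List[PeakFit]
    ) -> List[PeakFit]:
        """Strip the model residual for components missed on the first pass."""
        centers = hist.channel_centers
        residual = hist.channel_counts.astype(float)
        for p in fits:
            amp = p.area / (p.sd * np.sqrt(2.0 * np.pi))
            residual = residual - _gaussian(centers, amp, p.position, p.sd)
        sub = FcmHistogram(
            np.maximum(np.rint(residual), 0).astype(np.int64), gain=hist.gain
        )
        if sub.total() < self.min_peak_events:
            return []
        missed = []
        for q in self._strip(sub):
            if q.area < self.min_peak_events or q.cv > self.cv_max:
                continue
            if any(
                abs(q.position - p.position) < max(1.0, p.sd, q.sd)
                for p in fits
            ):
                continue
            missed.append(q)
        return missed

    # -- estimator surface --------------------------------------------------

    def fit(self, hist: FcmHistogram, y=None) -> "GaussianPeakDetector":
        if not isinstance(hist, FcmHistogram):
            raise ParameterError("GaussianPeakDetector.fit expects an FcmHistogram")
        counts = hist.channel_counts
        self.dropped_ = []
        if counts.sum() == 0:
            raise NoPeaksError("histogram is empty")
        fits = self._strip(hist)
        if not fits and not self.dropped_:
            raise NoPeaksError("no candidate peaks above the amplitude floor")

        def _quality_filter(fits: List[PeakFit]) -> List[PeakFit]:
            kept: List[PeakFit] = []
            for p in fits:
                if p.area < self.min_peak_events:
                    self.dropped_.append(
                        (f"area {p.area:.0f} < min_peak_events", int(p.position))
                    )
                elif p.cv > self.cv_max:
                    self.dropped_.append(
                        (f"cv {p.cv:.3f} > cv_max", int(p.position))
                    )
                else:
                    kept.append(p)
            return kept

        def _dedup(fits: List[PeakFit]) -> List[PeakFit]:
            # components whose centers are closer than the wider spread
            # cannot represent resolvable peaks: keep the larger area
            fits = sorted(fits, key=lambda p: p.position)
            out: List[PeakFit] = []
            for p in fits:
                if out and abs(p.position - out[-1].position) < max(
                    1.0, p.sd, out[-1].sd
                ):
                    if p.area > out[-1].area:
                        out[-1] = p
                    continue
                out.append(p)
            return out

        fits = _dedup(_quality_filter(fits))
        fits = self._joint_refit(hist, fits)
        fits = _dedup(fits)
        # weak components can be absorbed by a neighbour on the first
        # pass; strip the model residual once more and refit jointly
        missed = self._strip_residual(hist, fits)
        if missed:
            fits = self._joint_refit(hist, fits + missed)
        dedup = _dedup(_quality_filter(fits))
        # flag (not split) overlapping pairs
        for a, b in zip(dedup, dedup[1:]):
            if b.position - a.position < 2.0 * (a.sd + b.sd):
                a.flags.add("merged")
                b.flags.add("merged")
        if not dedup:
            raise NoPeaksError(
                "all peak candidates rejected by area/CV quality gates"
            )
        self.peaks_ = dedup
        return self


def detect_peaks(
    hist: FcmHistogram,
    min_peak_events: int = 100,
    smooth_window: int = 9,
    cv_max: float = 0.10,
    min_amplitude: float = 2.0,
) -> List[PeakFit]:
    """Functional wrapper around :class:`GaussianPeakDetector`."""
    det = GaussianPeakDetector(
        smooth_window=smooth_window,
        min_peak_events=min_peak_events,
        cv_max=cv_max,
        min_amplitude=min_amplitude,
    )
    return [replace(p, flags=set(p.flags)) for p in det.fit(hist).peaks_]
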