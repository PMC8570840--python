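"""Synthetic flow-cytometry data with partial-endoreplication structure.

Each simulated tube is a mixture of

* a debris background: truncated exponential on [0, standard position],
* the internal-standard G1 peak: Gaussian at the standard's 2C with
  sd = CV * mean, and
* the sample endocycle series: Gaussians at 2C + k*P for k = 0..K with
  geometrically decaying areas (later endocycles hold fewer nuclei).

Intensities are emitted in linear channel units (pg divided by the gain),
mirroring an uncalibrated instrument axis: downstream analysis must recover
pg through the internal standard, exactly as with real data.  Everything is
driven by an explicit seed; identical parameters and seed give bit-identical
events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import List, Optional, Sequence

import numpy as np

from .errors import ParameterError
from .io import EventTable, PISUM, StandardDef

__all__ = [
    "SimulationParams",
    "CohortRow",
    "simulate_sample",
    "simulate_cohort",
]

#: Exponential scale of the debris tail, as a fraction of the standard
#: peak position.  Fixed: fast enough a decay that debris stresses, but
#: does not swamp, peak detection.
DEBRIS_SCALE_FRACTION = 0.2


@dataclass
class SimulationParams:
    """Nominal truth for one simulated tube.

    ``peak_weights`` are the relative areas of the sample peaks k = 0..K
    (default geometric decay with ratio 0.5); ``standard_fraction`` is the
    share of non-debris events in the standard peak; ``gain_pg_per_channel``
    maps pg to the instrument's arbitrary linear axis.
    """

    two_c_pg: float
    p_pg: float
    k_max: int = 3
    peak_weights: Optional[Sequence[float]] = None
    cv: float = 0.03
    standard: StandardDef = PISUM
    standard_fraction: float = 0.3
    debris_fraction: float = 0.05
    n_events: int = 5000
    gain_pg_per_channel: float = 0.05
    seed: int = 0
    with_side_scatter: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.p_pg < self.two_c_pg:
            raise ParameterError("requires 0 < P < 2C")
        if self.k_max < 0:
            raise ParameterError("k_max must be >= 0")
        if self.peak_weights is None:
            self.peak_weights = tuple(0.5**k for k in range(self.k_max + 1))
        else:
            self.peak_weights = tuple(float(w) for w in self.peak_weights)
        if len(self.peak_weights) != self.k_max + 1:
            raise ParameterError("need k_max + 1 peak weights")
        if any(w <= 0 for w in self.peak_weights):
            raise ParameterError("peak weights must be positive")
        if not 0 <= self.debris_fraction < 1:
            raise ParameterError("debris_fraction must lie in [0, 1)")
        if not 0 < self.standard_fraction < 1:
            raise ParameterError("standard_fraction must lie in (0, 1)")
        if self.cv <= 0:
            raise ParameterError("cv must be > 0")
        if self.n_events < 1:
            raise ParameterError("n_events must be >= 1")
        if self.gain_pg_per_channel <= 0:
            raise ParameterError("gain must be > 0")


def simulate_sample(params: SimulationParams) -> EventTable:
    """Draw one tube's events from the debris + standard + series mixture.

    Component sizes are multinomial draws of ``n_events`` over the stated
    fractions; peak events are Gaussian with sd = cv * mean.  The nominal
    truth (2C, P, K, CV, standard, component counts, seed) is stored in the
    metadata so downstream recovery can be scored.  A sample 2C peak within
    2*CV of the standard position triggers an overlap warning (the case that
    calls for a secondary standard) but still generates.
    """
    rng = np.random.default_rng(params.seed)
    gain = params.gain_pg_per_channel
    std_pos = params.standard.two_c_pg / gain
    sample_pos = [
        (params.two_c_pg + k * params.p_pg) / gain
        for k in range(params.k_max + 1)
    ]
    if abs(sample_pos[0] - std_pos) / std_pos < 2.0 * params.cv:
        warnings.warn(
            "sample 2C peak lies within 2*CV of the standard peak; "
            "consider a secondary standard",
            stacklevel=2,
        )

    w = np.asarray(params.peak_weights, dtype=float)
    w = w / w.sum()
    probs = np.concatenate(
        [
            [params.debris_fraction],
            [(1 - params.debris_fraction) * params.standard_fraction],
            (1 - params.debris_fraction) * (1 - params.standard_fraction) * w,
        ]
    )
    counts = rng.multinomial(params.n_events, probs)

    parts = []
    # debris: inverse-CDF draw from an exponential truncated to [0, std_pos]
    n_deb = counts[0]
    if n_deb:
        scale = DEBRIS_SCALE_FRACTION * std_pos
        u = rng.random(n_deb)
        cdf_max = 1.0 - np.exp(-std_pos / scale)
        parts.append(-scale * np.log1p(-u * cdf_max))
    means = [std_pos] + sample_pos
    for mean, n in zip(means, counts[1:]):
        if n:
            parts.append(rng.normal(mean, params.cv * mean, size=n))
    fl = np.clip(np.concatenate(parts), 0.0, None)

    ssc = None
    if params.with_side_scatter:
        ssc_parts = []
        if n_deb:
            ssc_parts.append(rng.exponential(200.0, size=n_deb))
        n_nuclei = int(counts[1:].sum())
        if n_nuclei:
            ssc_parts.append(
                np.clip(rng.normal(1000.0, 150.0, size=n_nuclei), 0.0, None)
            )
        ssc = np.concatenate(ssc_parts)

    order = rng.permutation(fl.size)
    fl = fl[order]
    if ssc is not None:
        ssc = ssc[order]

    truth = {
        "two_c_pg": params.two_c_pg,
        "p_pg": params.p_pg,
        "k_max": params.k_max,
        "cv": params.cv,
        "standard": params.standard.name,
        "standard_two_c_pg": params.standard.two_c_pg,
        "gain_pg_per_channel": gain,
        "component_counts": counts.tolist(),
        "seed": params.seed,
    }
    return EventTable(fl, ssc, meta={"truth": truth, "standard": params.standard.name})


@dataclass(frozen=True)
class CohortRow:
    """Population-level parameters of one taxon / lineage."""

    label: str
    gs_mean: float
    gs_sd: float
    p_mean: float
    p_sd: float
    n: int
    ploidy: int = 2
    standard: Optional[StandardDef] = None


def simulate_cohort(
    taxon_params: Sequence[CohortRow],
    base: SimulationParams,
    seed: int = 0,
) -> List[EventTable]:
    """Simulate a cohort: per-individual (2C, P) drawn around taxon means.

    Each individual's nominal (2C, P) is drawn from normals truncated at
    zero with the row's mean/sd; draws with P >= 2C (or non-positive) are
    redrawn up to 100 times before a parameter error.  Taxon label, ploidy
    and a per-individual sub-seed are carried in the metadata.
    """
    rng = np.random.default_rng(seed)
    tables: List[EventTable] = []
    for row in taxon_params:
        if row.gs_sd < 0 or row.p_sd < 0:
            raise ParameterError(f"{row.label}: sd must be >= 0")
        if row.n < 1:
            raise ParameterError(f"{row.label}: n must be >= 1")
        for i in range(row.n):
            for attempt in range(100):
                gs = rng.normal(row.gs_mean, row.gs_sd)
                p = rng.normal(row.p_mean, row.p_sd)
                if 0 < p < gs:
                    break
            else:
                raise ParameterError(
                    f"{row.label}: could not draw 0 < P < 2C in 100 attempts"
                )
            sub_seed = int(rng.integers(0, 2**31 - 1))
            params = replace(
                base,
                two_c_pg=gs,
                p_pg=p,
                seed=sub_seed,
                standard=row.standard or base.standard,
            )
            table = simulate_sample(params)
            table.meta["sample_id"] = f"{row.label}-{i + 1:03d}"
            table.meta["taxon"] = row.label
            table.meta["truth"]["ploidy"] = row.ploidy
            table.meta["truth"]["taxon"] = row.label
            tables.append(table)
    return tables
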