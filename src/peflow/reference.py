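"""Published reference values for the Neotinea study system.

The table below holds the per-lineage genome-size (2C) and
endoreplicated-part (P) statistics of the genus *Neotinea* (Orchidaceae):
mean and sd in pg, the per-lineage sample size, ploidy, and the printed
percentage P% = 100*P/2C.  Rows marked ``aggregate`` pool the lineage-level
rows of the same taxon.  These values parameterize the synthetic reference
cohort that the test-bench and the acceptance script analyze end to end.

Standards: lineages whose mean 2C lies close to the primary standard
(Pisum sativum, 2C = 8.76 pg) are simulated against the secondary standard
(Solanum pseudocapsicum, 2C = 2.57 pg) so that the standard and sample 2C
peaks never collide — the same operator decision the original measurements
document for N. maculata.  The cutoff is mean 2C < 1.5x the Pisum 2C.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

from .io import PISUM, SOLANUM, StandardDef
from .simulate import CohortRow

__all__ = [
    "ReferenceRow",
    "REFERENCE_TABLE",
    "reference_cohort_rows",
    "pick_standard",
]


@dataclass(frozen=True)
class ReferenceRow:
    taxon: str
    ploidy: int
    region: str  # '' for taxon-level rows
    gs_mean: float
    gs_sd: float
    p_mean: float
    p_sd: float
    p_percent: float  # printed value, 1 d.p.
    n: int
    aggregate: bool = False  # pools the lineage rows of the same taxon


#: Published per-lineage statistics (pg; P% at 1 d.p.).
REFERENCE_TABLE: Tuple[ReferenceRow, ...] = (
    ReferenceRow("N. commutata", 4, "", 19.46, 0.39, 7.06, 0.09, 36.3, 7),
    ReferenceRow("N. conica", 2, "", 28.14, 0.58, 3.64, 0.15, 12.9, 31),
    ReferenceRow("N. lactea", 2, "", 28.65, 1.43, 3.59, 0.17, 12.5, 60),
    ReferenceRow("N. maculata", 2, "", 7.12, 0.22, 2.89, 0.05, 40.6, 29),
    ReferenceRow("N. tridentata", 2, "", 11.24, 1.82, 3.55, 0.17, 31.6, 132, True),
    ReferenceRow("N. tridentata", 2, "Crete", 13.92, 0.52, 3.69, 0.20, 26.5, 9),
    ReferenceRow(
        "N. tridentata", 2, "E Mediterranean", 15.70, 0.54, 3.55, 0.10, 22.6, 13
    ),
    ReferenceRow("N. tridentata", 2, "Israel", 9.46, 0.30, 3.27, 0.19, 34.6, 4),
    ReferenceRow(
        "N. tridentata", 2, "rest of Europe", 10.49, 0.38, 3.55, 0.16, 33.8, 106
    ),
    ReferenceRow("N. tridentata", 3, "", 16.16, 1.14, 5.27, 0.17, 32.6, 2),
    ReferenceRow("N. ustulata", 2, "", 10.48, 0.36, 3.52, 0.09, 33.6, 88, True),
    ReferenceRow(
        "N. ustulata", 2, "var. ustulata", 10.46, 0.39, 3.53, 0.09, 33.7, 60
    ),
    ReferenceRow(
        "N. ustulata", 2, "var. aestivalis", 10.52, 0.29, 3.51, 0.09, 33.4, 28
    ),
)


def pick_standard(gs_mean_pg: float) -> StandardDef:
    """Choose the internal standard that keeps standard and 2C peaks apart."""
    if gs_mean_pg < 1.5 * PISUM.two_c_pg:
        return SOLANUM
    return PISUM


def reference_cohort_rows(
    standard: Optional[StandardDef] = None,
) -> List[CohortRow]:
    """Cohort rows for the non-aggregate reference lineages (349 individuals).

    When ``standard`` is None each lineage gets the standard chosen by
    :func:`pick_standard`; passing one forces it for every lineage.
    """
    rows: List[CohortRow] = []
    for r in REFERENCE_TABLE:
        if r.aggregate:
            continue
        label = r.taxon if not r.region else f"{r.taxon} ({r.region})"
        if r.taxon == "N. tridentata" and r.ploidy == 3:
            label = "N. tridentata (3x)"
        rows.append(
            CohortRow(
                label=label,
                gs_mean=r.gs_mean,
                gs_sd=r.gs_sd,
                p_mean=r.p_mean,
                p_sd=r.p_sd,
                n=r.n,
                ploidy=r.ploidy,
                standard=standard or pick_standard(r.gs_mean),
            )
        )
    return rows
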