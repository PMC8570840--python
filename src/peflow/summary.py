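"""Per-taxon aggregation and Tukey HSD compact letter groups.

``summarize`` turns per-individual measurements into one row per
(taxon, ploidy, region/variant) group — mean and sample sd of 2C and P,
P% recomputed from the stored means, n — and ``tukey_groups`` attaches
compact letters from pairwise Tukey HSD (Tukey–Kramer for unbalanced
groups): groups that are not significantly different share a letter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import LabelingError, ParameterError
from .model import SampleMeasurement

__all__ = ["TaxonSummary", "summarize", "tukey_groups", "TukeyLetters", "to_table"]


@dataclass
class TaxonSummary:
    """Machine twin of one summary-table row."""

    taxon: str
    ploidy: int
    region: str
    gs_mean: float
    gs_sd: float
    p_mean: float
    p_sd: float
    p_percent: float
    n: int
    gs_group: str = ""
    p_group: str = ""
    sd_defined: bool = True


def summarize(
    measurements: Sequence[SampleMeasurement],
    region_of=None,
) -> List[TaxonSummary]:
    """Aggregate measurements into (taxon, ploidy, region) summary rows.

    Means are arithmetic; sd uses the n-1 denominator and is zero-filled
    (and marked undefined) for singleton groups.  P% is always recomputed
    as 100 * p_mean / gs_mean, rounded to 1 d.p.  Rows come back sorted by
    taxon, then ploidy, then region.
    """
    if not measurements:
        return []
    rows = []
    for m in measurements:
        if m.taxon is None:
            raise LabelingError(f"measurement {m.sample_id!r} lacks a taxon label")
        if m.ploidy is None:
            raise LabelingError(
                f"measurement {m.sample_id!r} lacks a ploidy (run delineation)"
            )
        region = region_of(m) if region_of is not None else ""
        rows.append(
            {
                "taxon": m.taxon,
                "ploidy": int(m.ploidy),
                "region": region,
                "gs": m.two_c_pg,
                "p": m.p_pg,
            }
        )
    frame = pd.DataFrame(rows)
    out: List[TaxonSummary] = []
    for (taxon, ploidy, region), grp in frame.groupby(
        ["taxon", "ploidy", "region"], sort=True
    ):
        n = len(grp)
        gs_mean = float(grp["gs"].mean())
        p_mean = float(grp["p"].mean())
        sd_defined = n > 1
        out.append(
            TaxonSummary(
                taxon=taxon,
                ploidy=int(ploidy),
                region=region,
                gs_mean=gs_mean,
                gs_sd=float(grp["gs"].std(ddof=1)) if sd_defined else 0.0,
                p_mean=p_mean,
                p_sd=float(grp["p"].std(ddof=1)) if sd_defined else 0.0,
                p_percent=float(np.round(100.0 * p_mean / gs_mean, 1)),
                n=n,
                sd_defined=sd_defined,
            )
        )
    out.sort(key=lambda s: (s.taxon, s.ploidy, s.region))
    return out


# ---------------------------------------------------------------------------
# Tukey HSD and compact letter display


@dataclass
class TukeyLetters:
    """Result of :func:`tukey_groups`."""

    letters: Dict[str, str]
    anova_f: float
    anova_p: float
    excluded: List[str] = field(default_factory=list)
    rejected_pairs: List[tuple] = field(default_factory=list)


def _compact_letters(
    labels: Sequence[str],
    means: Dict[str, float],
    distinct: set,
) -> Dict[str, str]:
    """Greedy insert-and-absorb compact letter display.

    ``distinct`` holds frozensets of label pairs declared significantly
    different.  Letters are assigned by ascending group mean; columns
    (letter sets) are split on each significant pair and absorbed when they
    become subsets of another column.  Deterministic for a fixed ordering.
    """
    order = sorted(labels, key=lambda g: (means[g], g))
    columns: List[set] = [set(order)]
    pairs = sorted(
        (tuple(sorted(p, key=lambda g: (means[g], g))) for p in distinct),
        key=lambda p: (means[p[0]], means[p[1]], p),
    )
    for a, b in pairs:
        for col in [c for c in columns if a in c and b in c]:
            columns.remove(col)
            for drop in (a, b):
                new = col - {drop}
                if new and not any(new <= other for other in columns):
                    columns.append(new)
    # absorb columns that became subsets
    columns = [
        c for c in columns if not any(c < other for other in columns)
    ]
    columns.sort(key=lambda c: (min(means[g] for g in c), sorted(c)[0]))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in order}
    for letter, col in zip(alphabet, columns):
        for g in col:
            letters[g] += letter
    return {g: "".join(sorted(letters[g])) for g in order}


def tukey_groups(
    groups: Dict[str, Sequence[float]], alpha: float = 0.05
) -> TukeyLetters:
    """One-way ANOVA plus Tukey HSD letters over labeled observation groups.

    Groups with fewer than 2 observations are excluded with a warning.
    Pairwise comparisons use the studentized-range distribution with the
    Tukey–Kramer correction for unequal n.  When every group has zero
    within-group variance, pairs with unequal means are declared different
    outright (the studentized range degenerates).
    """
    usable = {}
    excluded = []
    for label, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size < 2:
            excluded.append(label)
            warnings.warn(
                f"group {label!r} has < 2 observations; excluded from HSD",
                stacklevel=2,
            )
        else:
            usable[label] = arr
    if len(usable) < 2:
        raise ParameterError("Tukey HSD needs at least 2 groups with n >= 2")

    labels = sorted(usable)
    means = {g: float(usable[g].mean()) for g in labels}
    within_ss = sum(((usable[g] - means[g]) ** 2).sum() for g in labels)

    if within_ss == 0.0:
        distinct = {
            frozenset((a, b))
            for i, a in enumerate(labels)
            for b in labels[i + 1 :]
            if means[a] != means[b]
        }
        anova_f, anova_p = np.inf, 0.0
        if not distinct:
            anova_f, anova_p = 0.0, 1.0
    else:
        anova_f, anova_p = stats.f_oneway(*(usable[g] for g in labels))
        values = np.concatenate([usable[g] for g in labels])
        codes = np.concatenate(
            [np.full(usable[g].size, g, dtype=object) for g in labels]
        )
        res = pairwise_tukeyhsd(values, codes, alpha=alpha)
        distinct = set()
        for (a, b), reject in zip(
            ((g1, g2) for i, g1 in enumerate(res.groupsunique)
             for g2 in res.groupsunique[i + 1 :]),
            res.reject,
        ):
            if reject:
                distinct.add(frozenset((a, b)))

    letters = _compact_letters(labels, means, distinct)
    return TukeyLetters(
        letters=letters,
        anova_f=float(anova_f),
        anova_p=float(anova_p),
        excluded=excluded,
        rejected_pairs=sorted(tuple(sorted(p)) for p in distinct),
    )


# ---------------------------------------------------------------------------
# table emission

_TABLE_COLUMNS = [
    "taxon",
    "ploidy",
    "region/var",
    "GS_mean",
    "GS_sd",
    "P_mean",
    "P_sd",
    "P_pct",
    "n",
    "GS_group",
    "P_group",
]


def to_table(summaries: Sequence[TaxonSummary], path, header_lines=()) -> None:
    """Write summaries as a tab-delimited table (pg at 2 d.p., P% at 1 d.p.)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write("\t".join(_TABLE_COLUMNS) + "\n")
        for s in summaries:
            fh.write(
                "\t".join(
                    [
                        s.taxon,
                        str(s.ploidy),
                        s.region,
                        f"{s.gs_mean:.2f}",
                        f"{s.gs_sd:.2f}" if s.sd_defined else "",
                        f"{s.p_mean:.2f}",
                        f"{s.p_sd:.2f}" if s.sd_defined else "",
                        f"{s.p_percent:.1f}",
                        str(s.n),
                        s.gs_group,
                        s.p_group,
                    ]
                )
                + "\n"
            )


def attach_letters(
    summaries: Sequence[TaxonSummary],
    measurements: Sequence[SampleMeasurement],
    region_of=None,
    alpha: float = 0.05,
    base_ploidy: int = 2,
) -> List[TaxonSummary]:
    """Attach GS/P HSD letters to the diploid summary rows (on individuals)."""
    key_of = {}
    for m in measurements:
        region = region_of(m) if region_of is not None else ""
        key_of.setdefault((m.taxon, int(m.ploidy), region), []).append(m)
    gs_groups, p_groups = {}, {}
    for s in summaries:
        if s.ploidy != base_ploidy or s.n < 2:
            continue
        key = (s.taxon, s.ploidy, s.region)
        label = f"{s.taxon}|{s.region}"
        gs_groups[label] = [m.two_c_pg for m in key_of.get(key, [])]
        p_groups[label] = [m.p_pg for m in key_of.get(key, [])]
    if len(gs_groups) >= 2:
        gs_letters = tukey_groups(gs_groups, alpha=alpha).letters
        p_letters = tukey_groups(p_groups, alpha=alpha).letters
        out = []
        for s in summaries:
            label = f"{s.taxon}|{s.region}"
            if s.ploidy == base_ploidy and label in gs_letters:
                s = TaxonSummary(**{**s.__dict__})
                s.gs_group = gs_letters[label]
                s.p_group = p_letters[label]
            out.append(s)
        return out
    return list(summaries)
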