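"""Basic diagnostic plots: per-tube histogram and the 2C-vs-P scatter."""

from __future__ import annotations

from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .io import FcmHistogram
from .model import SampleMeasurement
from .peaks import PeakFit

__all__ = ["plot_histogram", "plot_gs_vs_p"]


def plot_histogram(
    hist: FcmHistogram,
    peaks: Optional[Sequence[PeakFit]] = None,
    path=None,
    title: str = "",
):
    """Render the fluorescence histogram with fitted peaks marked."""
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.step(hist.channel_centers, hist.channel_counts, where="mid", lw=0.8)
    if peaks:
        for p in peaks:
            label = p.role
            if p.role == "sample":
                label = f"2C + {p.k}P" if p.k else "2C"
            ax.axvline(p.position, color="crimson", ls="--", lw=0.8)
            ax.annotate(
                label,
                (p.position, hist.channel_counts.max() * 0.95),
                rotation=90,
                fontsize=8,
                ha="right",
            )
    ax.set_xlabel("fluorescence (channel)")
    ax.set_ylabel("events")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_gs_vs_p(
    measurements: Sequence[SampleMeasurement], path=None
):
    """Scatter of genome size (2C) against endoreplicated-part size (P)."""
    fig, ax = plt.subplots(figsize=(6, 5))
    taxa = sorted({m.taxon or "?" for m in measurements})
    cmap = plt.get_cmap("tab10")
    for i, taxon in enumerate(taxa):
        xs = [m.two_c_pg for m in measurements if (m.taxon or "?") == taxon]
        ys = [m.p_pg for m in measurements if (m.taxon or "?") == taxon]
        ax.scatter(xs, ys, s=12, color=cmap(i % 10), label=taxon, alpha=0.7)
    ax.set_xlabel("genome size 2C (pg)")
    ax.set_ylabel("endoreplicated part P (pg)")
    ax.legend(fontsize=7, loc="best")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
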