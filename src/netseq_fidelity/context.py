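"""Hotspot calling and sequence-context analysis.

A hotspot is a genomic position accumulating strictly more than a threshold
number (default >50) of 3'-terminal misincorporation events. Context windows
are reported in transcript space with the misincorporated position at index
0: negative offsets are RNA bases already transcribed (-1 = the preceding
base), positive offsets (+1, +2, ...) are template positions not yet
transcribed, read from the non-template strand in transcript orientation.
A position frequency matrix over the context windows is the numeric core of
a sequence logo.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import Interval, ReferenceGenome, revcomp, write_bed

DEFAULT_MIN_COUNT = 50
DEFAULT_HALFWIDTH = 5


@dataclass(frozen=True)
class Hotspot:
    contig: str
    position: int  # 0-based forward coordinate of the misincorporated base
    strand: str
    substitution: str  # template>read, or 'all' when pooled
    event_count: int
    context: str  # transcript-space window, centre index = halfwidth


def extract_context(
    genome: ReferenceGenome,
    contig: str,
    position: int,
    strand: str,
    halfwidth: int = DEFAULT_HALFWIDTH,
) -> str:
    """Transcript-space sequence window centred on ``position``.

    Plus strand: genome[position-h .. position+h]. Minus strand: reverse
    complement of the forward slice, so index ``halfwidth - 1`` is the base
    preceding the centre in the RNA. Windows running off a linear contig are
    padded with N placeholders; circular contigs wrap.
    """
    window = genome.fetch(contig, position - halfwidth, position + halfwidth + 1)
    return window if strand == "+" else revcomp(window)


def call_hotspots(
    events: pd.DataFrame,
    genome: ReferenceGenome | None = None,
    substitution: str = "G>A",
    min_count: int = DEFAULT_MIN_COUNT,
    halfwidth: int = DEFAULT_HALFWIDTH,
) -> list[Hotspot]:
    """Positions with strictly more than ``min_count`` offset-0 events.

    ``substitution`` selects one template>read class (the threshold is then
    applied per class at each position); ``"all"`` pools classes per
    position. Context windows are filled when a genome is supplied.
    """
    at3 = events[events["offset"] == 0]
    if len(at3) == 0:
        return []
    if substitution != "all":
        at3 = at3[at3["substitution"] == substitution]
        keys = ["contig", "position", "strand", "substitution"]
    else:
        keys = ["contig", "position", "strand"]
    grouped = at3.groupby(keys).size()
    hotspots = []
    for key, count in grouped.items():
        if count <= min_count:
            continue
        contig, position, strand = key[0], int(key[1]), key[2]
        sub = key[3] if substitution != "all" else "all"
        context = (
            extract_context(genome, contig, position, strand, halfwidth)
            if genome is not None
            else ""
        )
        hotspots.append(Hotspot(contig, position, strand, sub, int(count), context))
    hotspots.sort(key=lambda h: (h.contig, h.position, h.strand))
    return hotspots


@dataclass
class PositionFrequencyMatrix:
    """Per-column base frequencies of aligned context windows.

    ``frequencies`` is 4 x width (rows A, C, G, T); every column sums to 1
    except columns where all windows held N, which are NaN and listed in
    ``missing_columns``. Column labels run -halfwidth .. +halfwidth.
    """

    frequencies: np.ndarray
    n_sequences: int
    counts: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        sums = self.frequencies.sum(axis=0)
        ok = ~np.isnan(sums)
        if ok.any() and np.abs(sums[ok] - 1.0).max() > 1e-9:
            raise ValueError("PFM columns must sum to 1")

    @property
    def width(self) -> int:
        return self.frequencies.shape[1]

    @property
    def halfwidth(self) -> int:
        return (self.width - 1) // 2

    @property
    def missing_columns(self) -> list[int]:
        return list(np.nonzero(np.isnan(self.frequencies.sum(axis=0)))[0])

    def frequency(self, offset: int, base: str) -> float:
        return float(self.frequencies["ACGT".index(base), offset + self.halfwidth])

    def to_frame(self) -> pd.DataFrame:
        cols = [str(o) for o in range(-self.halfwidth, self.halfwidth + 1)]
        return pd.DataFrame(self.frequencies, index=list("ACGT"), columns=cols)


def position_frequency_matrix(contexts: Sequence[str]) -> PositionFrequencyMatrix:
    """Column-wise base frequencies; N entries drop out of that column's denominator."""
    if not contexts:
        raise ValueError("at least one context window required")
    width = len(contexts[0])
    if any(len(c) != width for c in contexts):
        raise ValueError("context windows must have equal lengths")
    counts = np.zeros((4, width), dtype=np.int64)
    for ctx in contexts:
        for j, b in enumerate(ctx.upper()):
            if b in "ACGT":
                counts["ACGT".index(b), j] += 1
    denom = counts.sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        freqs = np.where(denom > 0, counts / np.maximum(denom, 1), np.nan)
    return PositionFrequencyMatrix(freqs, len(contexts), counts)


def hotspot_contexts(hotspots: Sequence[Hotspot]) -> list[str]:
    return [h.context for h in hotspots if h.context]


def write_hotspots_bed(hotspots: Sequence[Hotspot], path: str | Path) -> None:
    intervals = [Interval(h.contig, h.position, h.position + 1, h.strand) for h in hotspots]
    names = [f"{h.substitution}:{h.event_count}" for h in hotspots]
    write_bed(path, intervals, names)


def hotspots_frame(hotspots: Sequence[Hotspot]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (h.contig, h.position + 1, h.strand, h.substitution, h.event_count, h.context)
            for h in hotspots
        ],
        columns=["contig", "pos", "strand", "substitution", "event_count", "context"],
    )


def plot_logo(pfm: PositionFrequencyMatrix, path: str | Path) -> None:
    """Frequency logo: stacked per-column letter heights (matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}
    fig, ax = plt.subplots(figsize=(max(4, pfm.width * 0.6), 3))
    offsets = np.arange(-pfm.halfwidth, pfm.halfwidth + 1)
    for j, off in enumerate(offsets):
        col = pfm.frequencies[:, j]
        if np.isnan(col).any():
            continue
        bottom = 0.0
        for bi in np.argsort(col):
            f = float(col[bi])
            if f <= 0:
                continue
            base = "ACGT"[bi]
            ax.bar(off, f, bottom=bottom, color=colors[base], width=0.8)
            ax.text(
                off,
                bottom + f / 2,
                base,
                ha="center",
                va="center",
                fontsize=7 + 10 * f,
                color="white",
                fontweight="bold",
            )
            bottom += f
    ax.set_xlabel("offset from misincorporated position")
    ax.set_ylabel("base frequency")
    ax.set_xticks(offsets)
    ax.set_ylim(0, 1)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
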