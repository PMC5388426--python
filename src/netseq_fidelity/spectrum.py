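"""Per-position error rates of nascent-RNA 3' ends.

For every aligned read and every offset 0..-(window-1) from the 3' terminus,
a denominator counts the read when its base there is not N; a mismatch event
is emitted when the transcript-space read base differs from the reference,
neither base is N, the call passes the Phred threshold, and the position is
not a known strain variant. Total and 12-class specific rates per offset are
the central readout: the offset-0 total rate is the proportion of elongation
complexes whose nascent RNA carries a 3'-terminal misincorporation.

Substitution labels are template>read in transcript space: "G>A" means an A
was incorporated where the template dictated G.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._stacking import StackedAlignments, stack_alignments
from .align import Alignment
from .genome import N_CODE, ReferenceGenome
from .preprocess import ReadRecord
from .varmask import VariantSet

DEFAULT_PHRED_MIN = 30
DEFAULT_WINDOW = 11  # offsets 0..-10, the approximate RNA/DNA hybrid length

SUBSTITUTIONS = tuple(f"{t}>{r}" for t in "ACGT" for r in "ACGT" if t != r)

EVENT_COLUMNS = (
    "read_id",
    "contig",
    "position",
    "strand",
    "offset",
    "template_base",
    "read_base",
    "quality",
    "substitution",
)

_BASES = "ACGTN"


def _empty_events() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": pd.Series(dtype=str),
            "contig": pd.Series(dtype=str),
            "position": pd.Series(dtype=np.int64),
            "strand": pd.Series(dtype=str),
            "offset": pd.Series(dtype=np.int64),
            "template_base": pd.Series(dtype=str),
            "read_base": pd.Series(dtype=str),
            "quality": pd.Series(dtype=np.int64),
            "substitution": pd.Series(dtype=str),
        }
    )


def extract_mismatch_events(
    alignments: Sequence[Alignment],
    reads_by_id: Mapping[str, ReadRecord],
    genome: ReferenceGenome,
    variants: VariantSet | None = None,
    phred_min: int = DEFAULT_PHRED_MIN,
    window: int = DEFAULT_WINDOW,
    quality_in_denominator: bool = False,
    stacked: StackedAlignments | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Quality-passing mismatch calls plus per-offset denominators.

    ``denominators[k]`` counts reads with a non-N called base at offset -k.
    By default the denominator ignores base quality — only the mismatch
    classification is Phred-thresholded; set ``quality_in_denominator`` to
    also require the threshold of matched bases.
    """
    if phred_min < 0:
        raise ValueError("phred_min must be >= 0")
    if window < 1:
        raise ValueError("window must be >= 1")
    if stacked is None:
        stacked = stack_alignments(alignments, reads_by_id, genome)

    in_window = stacked.offsets > -window
    offs = stacked.offsets[in_window]
    read_c = stacked.read_codes[in_window]
    tmpl_c = stacked.tmpl_codes[in_window]
    quals = stacked.quals[in_window]
    pos = stacked.genomic_pos[in_window]
    contig_i = stacked.contig_index[in_window]
    strand_p = stacked.strand_plus[in_window]
    read_i = stacked.read_index[in_window]

    denom_ok = read_c != N_CODE
    if quality_in_denominator:
        denom_ok &= quals >= phred_min
    denominators = np.bincount(-offs[denom_ok], minlength=window)[:window]

    mism = (
        (read_c != tmpl_c)
        & (read_c != N_CODE)
        & (tmpl_c != N_CODE)
        & (quals >= phred_min)
    )
    if variants is not None and len(variants) > 0:
        for ci, name in enumerate(stacked.contigs):
            vpos = variants.positions(name)
            if len(vpos):
                hit = (contig_i == ci) & np.isin(pos, vpos)
                mism &= ~hit

    idx = np.nonzero(mism)[0]
    if len(idx) == 0:
        return _empty_events(), denominators

    tmpl_b = np.array(list(_BASES))[tmpl_c[idx]]
    read_b = np.array(list(_BASES))[read_c[idx]]
    events = pd.DataFrame(
        {
            "read_id": [stacked.read_ids[k] for k in read_i[idx]],
            "contig": [stacked.contigs[k] for k in contig_i[idx]],
            "position": pos[idx],
            "strand": np.where(strand_p[idx], "+", "-"),
            "offset": offs[idx],
            "template_base": tmpl_b,
            "read_base": read_b,
            "quality": quals[idx],
            "substitution": np.char.add(np.char.add(tmpl_b, ">"), read_b),
        }
    )
    return events, denominators


@dataclass
class PositionalErrorTable:
    """Per-offset denominators, total rates, and 12-class specific rates.

    Index ``k`` corresponds to offset ``-k``. Rates are percentages of the
    denominator at that offset; a zero denominator yields NaN (reported as
    missing rather than zero).
    """

    window: int
    denominators: np.ndarray
    mismatch_reads: np.ndarray
    specific_counts: pd.DataFrame  # rows: offsets 0..-(W-1); cols: 12 labels

    def __post_init__(self) -> None:
        if (self.specific_counts.sum(axis=1).to_numpy() != self.mismatch_reads).any():
            raise ValueError("specific counts do not sum to mismatch counts")

    @property
    def offsets(self) -> np.ndarray:
        return -np.arange(self.window)

    @property
    def total_rate_percent(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            rate = 100.0 * self.mismatch_reads / self.denominators
        return np.where(self.denominators > 0, rate, np.nan)

    def total_rate(self, offset: int) -> float:
        return float(self.total_rate_percent[-offset])

    def specific_rate_percent(self) -> pd.DataFrame:
        denom = self.denominators.astype(float)
        denom[denom == 0] = np.nan
        return 100.0 * self.specific_counts.div(denom, axis=0)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "offset": self.offsets,
                "denominator_reads": self.denominators,
                "mismatch_reads": self.mismatch_reads,
                "total_rate_percent": self.total_rate_percent,
            }
        )
        return pd.concat([frame, self.specific_counts.reset_index(drop=True)], axis=1)

    def to_dict(self) -> dict:
        frame = self.to_frame()
        return {
            "window": self.window,
            "rows": frame.replace({np.nan: None}).to_dict(orient="records"),
        }


def positional_error_table(
    events: pd.DataFrame, denominators: np.ndarray
) -> PositionalErrorTable:
    """Aggregate mismatch events into the per-offset rate table."""
    window = len(denominators)
    mismatch_reads = np.zeros(window, dtype=np.int64)
    counts = pd.DataFrame(
        0, index=range(window), columns=list(SUBSTITUTIONS), dtype=np.int64
    )
    if not events.empty:
        grouped = events.groupby([-events["offset"], "substitution"]).size()
        for (k, sub), c in grouped.items():
            if k < window:
                counts.loc[k, sub] = c
        mismatch_reads = counts.sum(axis=1).to_numpy()
    return PositionalErrorTable(window, np.asarray(denominators), mismatch_reads, counts)


def misincorporated_ec_fraction(table: PositionalErrorTable) -> float:
    """Percentage of ECs with a 3'-terminal mismatch: total rate at offset 0."""
    if table.denominators[0] == 0:
        raise ValueError("no reads with a called base at offset 0")
    return table.total_rate(0)


def threshold_sweep(
    events: pd.DataFrame, thresholds: Sequence[int] | None = None
) -> pd.DataFrame:
    """Positions and ECs surviving a per-position event-count threshold.

    Offset-0 events are grouped by (contig, position, strand), pooling
    substitution types; for each threshold t the sweep reports how many
    distinct positions carry strictly more than t events and how many events
    (ECs) those positions hold. Both series are non-increasing in t.
    """
    at3 = events[events["offset"] == 0] if not events.empty else events
    if at3 is None or len(at3) == 0:
        counts = np.array([], dtype=np.int64)
    else:
        counts = (
            at3.groupby(["contig", "position", "strand"]).size().to_numpy()
        )
    max_count = int(counts.max()) if len(counts) else 0
    if thresholds is None:
        thresholds = range(max_count + 1)
    rows = []
    for t in thresholds:
        above = counts > t
        rows.append((int(t), int(above.sum()), int(counts[above].sum())))
    return pd.DataFrame(rows, columns=["threshold", "n_positions", "n_ecs"])


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    """Events as TSV with 1-based positions."""
    out = events.copy()
    out["position"] = out["position"] + 1
    out = out[
        ["contig", "position", "strand", "offset", "template_base", "read_base",
         "quality", "read_id"]
    ]
    out.columns = ["contig", "pos", "strand", "offset", "tmpl", "obs", "qual", "read_id"]
    out.to_csv(path, sep="\t", index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    raw = pd.read_csv(path, sep="\t", dtype={"tmpl": str, "obs": str})
    events = pd.DataFrame(
        {
            "read_id": raw["read_id"],
            "contig": raw["contig"],
            "position": raw["pos"] - 1,
            "strand": raw["strand"],
            "offset": raw["offset"],
            "template_base": raw["tmpl"],
            "read_base": raw["obs"],
            "quality": raw["qual"],
            "substitution": raw["tmpl"] + ">" + raw["obs"],
        }
    )
    return events
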