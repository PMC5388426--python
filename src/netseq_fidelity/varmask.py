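"""Strain-vs-reference variant identification and masking.

A laboratory strain differs from its reference genome at a handful of
positions; without masking, every read over such a position would be scored
as a mismatch and inflate the misincorporation rate. Variants are called
from a strand-pooled pileup with a depth/fraction threshold caller (planted
or real homozygous variants show near-100% alternative-base fractions, far
above any misincorporation signal), then excluded from all downstream
statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from ._stacking import StackedAlignments, stack_alignments
from .align import Alignment
from .genome import N_CODE, ReferenceGenome, encode
from .preprocess import ReadRecord

logger = logging.getLogger(__name__)

BASE_ORDER = "ACGTN"


@dataclass
class PileupColumns:
    """Strand-resolved base counts per genomic position, one array per contig.

    ``counts[contig]`` has shape (2, 5, L): strand (+,-) x base (A,C,G,T,N)
    x position. Base identities are expressed on the forward genome strand
    (minus-strand read bases are complemented), so pooled counts compare
    directly against the reference. N bases are tallied but excluded from
    the calling depth.
    """

    counts: dict[str, np.ndarray]

    def depth(self, contig: str) -> np.ndarray:
        """Calling depth per position: non-N bases pooled over strands."""
        return self.counts[contig][:, :4, :].sum(axis=(0, 1))

    def column(self, contig: str, position: int) -> dict[str, int]:
        pooled = self.counts[contig][:, :, position].sum(axis=0)
        return {b: int(c) for b, c in zip(BASE_ORDER, pooled)}


class Variant(NamedTuple):
    contig: str
    position: int  # 0-based
    ref: str
    alt: str
    alt_fraction: float
    depth: int


@dataclass
class VariantSet:
    """Called single-base variants, indexed for fast position lookup."""

    variants: list[Variant] = field(default_factory=list)

    def __post_init__(self) -> None:
        for v in self.variants:
            if v.alt == v.ref:
                raise ValueError(f"variant at {v.position} has alt == ref")
            if not 0 < v.alt_fraction <= 1:
                raise ValueError("alt_fraction outside (0, 1]")
        self._positions = frozenset((v.contig, v.position) for v in self.variants)

    def __len__(self) -> int:
        return len(self.variants)

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self._positions

    def positions(self, contig: str) -> np.ndarray:
        return np.array(
            sorted(v.position for v in self.variants if v.contig == contig),
            dtype=np.int64,
        )


def pileup(
    alignments: Sequence[Alignment],
    reads_by_id: Mapping[str, ReadRecord],
    genome: ReferenceGenome,
    stacked: StackedAlignments | None = None,
) -> PileupColumns:
    """Tally every aligned read base into its genomic column."""
    if stacked is None:
        stacked = stack_alignments(alignments, reads_by_id, genome)
    counts = {
        name: np.zeros((2, 5, len(seq)), dtype=np.int64)
        for name, seq in genome.contigs.items()
    }
    # forward-strand base identity: complement minus-strand read bases
    fwd_codes = stacked.read_codes.astype(np.int64).copy()
    minus = ~stacked.strand_plus
    compl = np.array([3, 2, 1, 0, 4], dtype=np.int64)
    fwd_codes[minus] = compl[fwd_codes[minus]]
    strand_idx = np.where(stacked.strand_plus, 0, 1)
    for ci, name in enumerate(stacked.contigs):
        sel = stacked.contig_index == ci
        if not sel.any():
            continue
        flat = counts[name].reshape(-1)
        L = counts[name].shape[2]
        flat_idx = (strand_idx[sel] * 5 + fwd_codes[sel]) * L + stacked.genomic_pos[sel]
        np.add.at(flat, flat_idx, 1)
    return PileupColumns(counts)


def call_variants(
    columns: PileupColumns,
    genome: ReferenceGenome,
    min_depth: int = 10,
    min_alt_fraction: float = 0.8,
) -> VariantSet:
    """Depth/fraction threshold caller over strand-pooled columns.

    A position is a variant iff its non-N depth is >= ``min_depth`` and the
    single most frequent non-reference base reaches ``min_alt_fraction`` of
    that depth. At most one variant per position.
    """
    variants: list[Variant] = []
    for contig, arr in columns.counts.items():
        pooled = arr[:, :4, :].sum(axis=0)  # (4, L)
        depth = pooled.sum(axis=0)
        ref_codes = encode(genome.contigs[contig]).astype(np.int64)
        nonref = pooled.copy()
        cols = np.arange(nonref.shape[1])
        valid_ref = ref_codes < N_CODE
        nonref[ref_codes[valid_ref], cols[valid_ref]] = -1
        alt_codes = nonref.argmax(axis=0)
        alt_counts = nonref.max(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            alt_frac = np.where(depth > 0, alt_counts / np.maximum(depth, 1), 0.0)
        hit = (depth >= min_depth) & (alt_counts > 0) & (alt_frac >= min_alt_fraction)
        for pos in np.nonzero(hit)[0]:
            variants.append(
                Variant(
                    contig,
                    int(pos),
                    BASE_ORDER[ref_codes[pos]],
                    BASE_ORDER[alt_codes[pos]],
                    float(alt_frac[pos]),
                    int(depth[pos]),
                )
            )
    return VariantSet(variants)


def mask_events(events: pd.DataFrame, variants: VariantSet) -> pd.DataFrame:
    """Remove every event at a called variant position; log the removal count.

    Idempotent and order-independent: masking filters on (contig, position)
    membership only.
    """
    if len(variants) == 0 or events.empty:
        return events
    keys = list(zip(events["contig"], events["position"]))
    keep = np.array([key not in variants for key in keys])
    removed = int((~keep).sum())
    if removed:
        logger.info("masked %d events at %d variant positions", removed, len(variants))
    return events[keep].reset_index(drop=True)


def write_vcf(variants: VariantSet, path: str | Path) -> None:
    """Minimal VCF: CHROM, POS (1-based), REF, ALT, INFO DP/AF."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants.variants:
            fh.write(
                f"{v.contig}\t{v.position + 1}\t.\t{v.ref}\t{v.alt}\t.\t.\t"
                f"DP={v.depth};AF={v.alt_fraction:.4f}\n"
            )


def read_vcf(path: str | Path) -> VariantSet:
    variants = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            contig, pos, _, ref, alt, _, _, info = line.rstrip("\n").split("\t")[:8]
            fields = dict(kv.split("=") for kv in info.split(";"))
            variants.append(
                Variant(
                    contig,
                    int(pos) - 1,
                    ref,
                    alt,
                    float(fields.get("AF", 1.0)),
                    int(fields.get("DP", 0)),
                )
            )
    return VariantSet(variants)
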