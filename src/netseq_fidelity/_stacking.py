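"""Internal: flatten alignments + reads into per-base numpy arrays.

Shared by the pileup and the mismatch-event extraction so both operate on
one vectorised representation instead of nested Python loops.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .align import Alignment
from .genome import COMPLEMENT_CODE, ReferenceGenome, encode
from .preprocess import ReadRecord


@dataclass
class StackedAlignments:
    """Flat per-base view of a set of ungapped alignments.

    All arrays have one entry per aligned read base. ``tmpl_codes`` holds the
    transcript-space reference base (complemented for minus-strand reads);
    ``read_codes`` the transcript-space read base; ``offsets`` the position
    relative to the 3' terminus (0, -1, ...); ``genomic_pos`` the forward
    genome coordinate.
    """

    contigs: list[str]
    read_ids: list[str]
    read_index: np.ndarray
    contig_index: np.ndarray
    strand_plus: np.ndarray
    genomic_pos: np.ndarray
    offsets: np.ndarray
    read_codes: np.ndarray
    tmpl_codes: np.ndarray
    quals: np.ndarray

    @property
    def n_bases(self) -> int:
        return len(self.read_codes)

    @property
    def n_reads(self) -> int:
        return len(self.read_ids)


def stack_alignments(
    alignments: Sequence[Alignment],
    reads_by_id: Mapping[str, ReadRecord],
    genome: ReferenceGenome,
) -> StackedAlignments:
    contigs = list(genome.contigs)
    contig_idx = {name: i for i, name in enumerate(contigs)}
    enc = {name: encode(seq) for name, seq in genome.contigs.items()}

    total = sum(a.read_length for a in alignments)
    read_index = np.empty(total, dtype=np.int64)
    contig_index = np.empty(total, dtype=np.int64)
    strand_plus = np.empty(total, dtype=bool)
    genomic_pos = np.empty(total, dtype=np.int64)
    offsets = np.empty(total, dtype=np.int64)
    read_codes = np.empty(total, dtype=np.uint8)
    tmpl_codes = np.empty(total, dtype=np.uint8)
    quals = np.empty(total, dtype=np.int64)

    read_ids = []
    cursor = 0
    for k, aln in enumerate(alignments):
        read = reads_by_id[aln.read_id]
        rl = aln.read_length
        if len(read) != rl:
            raise ValueError(f"{aln.read_id}: read length differs from alignment")
        ref = enc[aln.contig]
        n = len(ref)
        sl = slice(cursor, cursor + rl)
        i = np.arange(rl)
        read_ids.append(aln.read_id)
        read_index[sl] = k
        contig_index[sl] = contig_idx[aln.contig]
        strand_plus[sl] = aln.strand == "+"
        offsets[sl] = i - (rl - 1)
        if aln.strand == "+":
            pos = aln.start + i
        else:
            pos = aln.start + (rl - 1 - i)
        if aln.start + rl > n:
            if not genome.circular.get(aln.contig, False):
                raise ValueError(f"{aln.read_id}: alignment outside linear contig")
            pos = pos % n
        genomic_pos[sl] = pos
        ref_codes = ref[pos]
        tmpl_codes[sl] = (
            ref_codes if aln.strand == "+" else COMPLEMENT_CODE[ref_codes]
        )
        read_codes[sl] = encode(read.sequence)
        quals[sl] = read.qualities
        cursor += rl

    return StackedAlignments(
        contigs=contigs,
        read_ids=read_ids,
        read_index=read_index,
        contig_index=contig_index,
        strand_plus=strand_plus,
        genomic_pos=genomic_pos,
        offsets=offsets,
        read_codes=read_codes,
        tmpl_codes=tmpl_codes,
        quals=quals,
    )
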