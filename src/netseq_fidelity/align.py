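"""Unique, ungapped, seed-anchored short-read alignment.

Policy: the seed is the ``seed_len`` bases at the read's 3' end (the end
carrying any misincorporation); candidate placements are those where the
seed matches the genome with at most ``seed_mismatches`` substitutions, each
candidate is extended ungapped over the full read with no cap on mismatches
outside the seed, candidates are ranked by total mismatch count, and when
more than one placement ties in the best stratum the read is rejected as
multimapped (only unique alignments are reported).

Candidate generation partitions the seed into three parts; by the pigeonhole
principle any placement with <= 2 seed mismatches matches at least one part
exactly, so an exact-match index over the parts finds every candidate. A
k-mer uniqueness audit over both strands justifies the seed length choice.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .genome import COMPLEMENT_CODE, N_CODE, ReferenceGenome, encode, revcomp
from .preprocess import ReadRecord

DEFAULT_SEED_LEN = 14
DEFAULT_SEED_MISMATCHES = 2

#: bases of circular-origin padding appended to index arrays (bounds the
#: longest read a wrapped placement can carry)
CIRCULAR_PAD = 64


@dataclass
class AlignParams:
    seed_len: int = DEFAULT_SEED_LEN
    seed_mismatches: int = DEFAULT_SEED_MISMATCHES
    unique_only: bool = True


@dataclass
class Alignment:
    """An ungapped unique placement of a read on one contig strand.

    ``start`` is the leftmost forward-genome coordinate (0-based). For a
    minus-strand placement the transcript-space read equals the reverse
    complement of the forward slice. ``mismatch_offsets`` are read positions
    counted from the 3' end (0, -1, ...) where read != reference.
    """

    read_id: str
    contig: str
    start: int
    strand: str
    read_length: int
    mismatch_offsets: np.ndarray

    def __post_init__(self) -> None:
        self.mismatch_offsets = np.asarray(self.mismatch_offsets, dtype=np.int64)
        if len(self.mismatch_offsets) and self.mismatch_offsets.max() > 0:
            raise ValueError("mismatch offsets must be <= 0")

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatch_offsets)

    @property
    def genomic_3prime_position(self) -> int:
        """Forward coordinate of the nascent-RNA 3' terminus."""
        if self.strand == "+":
            return self.start + self.read_length - 1
        return self.start


@dataclass(frozen=True)
class Rejection:
    read_id: str
    reason: str  # too_short | unaligned | multimapped


@dataclass
class KmerUniquenessReport:
    k: int
    total_kmers: int
    distinct: int
    unique_fraction: float

    def __post_init__(self) -> None:
        if not 0 <= self.unique_fraction <= 1:
            raise ValueError("unique_fraction outside [0, 1]")
        if self.distinct > self.total_kmers:
            raise ValueError("distinct k-mers exceed total instances")


def kmer_uniqueness(genome: ReferenceGenome, k: int) -> KmerUniquenessReport:
    """Count every k-mer instance over both strands; N-containing excluded.

    ``unique_fraction`` is the fraction of instances whose sequence occurs
    exactly once over both strands (the quantity that justifies a seed
    length: a read seed of this length almost always has one origin).
    """
    if k < 1 or all(k > len(s) for s in genome.contigs.values()):
        raise ValueError(f"k={k} exceeds every contig length")
    counts: Counter[str] = Counter()
    for seq in genome.contigs.values():
        for strand_seq in (seq, revcomp(seq)):
            for i in range(len(strand_seq) - k + 1):
                kmer = strand_seq[i : i + k]
                if "N" not in kmer:
                    counts[kmer] += 1
    total = sum(counts.values())
    unique = sum(c for c in counts.values() if c == 1)
    return KmerUniquenessReport(
        k=k,
        total_kmers=total,
        distinct=len(counts),
        unique_fraction=(unique / total) if total else 0.0,
    )


def _part_bounds(seed_len: int) -> list[tuple[int, int]]:
    """Split the seed into 3 near-equal parts (pigeonhole for <=2 mismatches)."""
    base, rem = divmod(seed_len, 3)
    sizes = [base + (1 if i < rem else 0) for i in range(3)]
    bounds, off = [], 0
    for s in sizes:
        bounds.append((off, off + s))
        off += s
    return bounds


def _kmer_keys(codes: np.ndarray, off: int, length: int, n_positions: int) -> np.ndarray:
    """Integer key of codes[s+off : s+off+length] for s in [0, n_positions).

    Positions whose window contains N get key -1.
    """
    keys = np.zeros(n_positions, dtype=np.int64)
    valid = np.ones(n_positions, dtype=bool)
    for j in range(length):
        col = codes[off + j : off + j + n_positions].astype(np.int64)
        keys = keys * 4 + np.minimum(col, 3)
        valid &= col < N_CODE
    keys[~valid] = -1
    return keys


class _StrandIndex:
    """Sorted-key exact lookup over the 3 seed parts of one strand array."""

    def __init__(self, codes: np.ndarray, seed_len: int, n_real: int):
        self.codes = codes
        self.n_real = n_real  # contig length before circular padding
        n_pos = len(codes) - seed_len + 1
        self.parts = []
        for off, end in _part_bounds(seed_len):
            keys = _kmer_keys(codes, off, end - off, n_pos)
            order = np.argsort(keys, kind="stable")
            self.parts.append((keys[order], order.astype(np.int64)))
        # full-seed exact index: fast path for error-free placements
        full_keys = _kmer_keys(codes, 0, seed_len, n_pos)
        order = np.argsort(full_keys, kind="stable")
        self.full = (full_keys[order], order.astype(np.int64))

    def exact_candidates(self, key: int) -> np.ndarray:
        if key < 0:
            return np.empty(0, dtype=np.int64)
        sorted_keys, positions = self.full
        lo = np.searchsorted(sorted_keys, key, side="left")
        hi = np.searchsorted(sorted_keys, key, side="right")
        return positions[lo:hi]

    def candidates(self, part_keys: Sequence[int]) -> np.ndarray:
        """Seed-start positions whose window exactly matches any part."""
        hits = []
        for (sorted_keys, positions), key in zip(self.parts, part_keys):
            if key < 0:
                continue
            lo = np.searchsorted(sorted_keys, key, side="left")
            hi = np.searchsorted(sorted_keys, key, side="right")
            if hi > lo:
                hits.append(positions[lo:hi])
        if not hits:
            return np.empty(0, dtype=np.int64)
        return np.unique(np.concatenate(hits))


class GenomeIndex:
    """Exact-match part index over fixed-length seeds of both strands."""

    def __init__(self, genome: ReferenceGenome, seed_len: int = DEFAULT_SEED_LEN):
        self.genome = genome
        self.seed_len = seed_len
        self._part_bounds = _part_bounds(seed_len)
        self._strands: dict[tuple[str, str], _StrandIndex] = {}
        for name, seq in genome.contigs.items():
            fwd = encode(seq)
            rev = COMPLEMENT_CODE[fwd][::-1].copy()
            if genome.circular.get(name, False):
                pad = CIRCULAR_PAD
                fwd = np.concatenate([fwd, fwd[:pad]])
                rev = np.concatenate([rev, rev[:pad]])
            self._strands[(name, "+")] = _StrandIndex(fwd, seed_len, len(seq))
            self._strands[(name, "-")] = _StrandIndex(rev, seed_len, len(seq))

    def read_part_keys(self, seed_codes: np.ndarray) -> list[int]:
        keys = []
        for off, end in self._part_bounds:
            window = seed_codes[off:end].astype(np.int64)
            if (window >= N_CODE).any():
                keys.append(-1)
            else:
                key = 0
                for c in window:
                    key = key * 4 + int(c)
                keys.append(key)
        return keys


def align_read(
    read: ReadRecord,
    index: GenomeIndex,
    params: AlignParams | None = None,
) -> Alignment | Rejection:
    """Place one transcript-space read; reject too_short / unaligned / multimapped."""
    params = params or AlignParams()
    if params.seed_len != index.seed_len:
        raise ValueError("params.seed_len differs from the index seed length")
    rl = len(read)
    if rl < params.seed_len:
        return Rejection(read.read_id, "too_short")

    read_codes = encode(read.sequence)
    seed_codes = read_codes[rl - params.seed_len :]
    seed_off = rl - params.seed_len
    has_n = bool((read_codes == N_CODE).any())

    def _bounded(q: np.ndarray, sidx: _StrandIndex, contig: str) -> np.ndarray:
        if index.genome.circular.get(contig, False):
            q = np.unique(q % sidx.n_real)
            return q[q + rl <= len(sidx.codes)]
        return q[(q >= 0) & (q + rl <= sidx.n_real)]

    def _mismatch_rows(windows: np.ndarray) -> np.ndarray:
        # N on either side never matches
        return (windows != read_codes) | (windows == N_CODE) | (read_codes == N_CODE)

    # fast path: a zero-mismatch placement must carry an exact seed, and can
    # only be tied by other zero-mismatch (hence exact-seed) placements
    if not has_n:
        full_key = 0
        for c in seed_codes:
            full_key = full_key * 4 + int(c)
        perfect: list[tuple[str, str, int]] = []
        for (contig, strand), sidx in index._strands.items():
            q = _bounded(sidx.exact_candidates(full_key) - seed_off, sidx, contig)
            if not len(q):
                continue
            windows = sidx.codes[q[:, None] + np.arange(rl)]
            total = _mismatch_rows(windows).sum(axis=1)
            perfect.extend((contig, strand, int(qq)) for qq in q[total == 0])
        if perfect:
            if params.unique_only and len(perfect) > 1:
                return Rejection(read.read_id, "multimapped")
            contig, strand, q0 = perfect[0]
            n_real = index._strands[(contig, strand)].n_real
            start = q0 if strand == "+" else (n_real - q0 - rl) % n_real
            return Alignment(
                read.read_id, contig, start, strand, rl, np.empty(0, dtype=np.int64)
            )

    part_keys = index.read_part_keys(seed_codes)
    best_mm = None
    best: list[tuple[str, str, int, np.ndarray]] = []  # contig, strand, q, mism row
    for (contig, strand), sidx in index._strands.items():
        s_cand = sidx.candidates(part_keys)
        if not len(s_cand):
            continue
        q = _bounded(s_cand - seed_off, sidx, contig)
        if not len(q):
            continue
        windows = sidx.codes[q[:, None] + np.arange(rl)]
        mism = _mismatch_rows(windows)
        seed_mm = mism[:, seed_off:].sum(axis=1)
        ok = seed_mm <= params.seed_mismatches
        if not ok.any():
            continue
        q, mism = q[ok], mism[ok]
        total = mism.sum(axis=1)
        for j in np.argsort(total, kind="stable"):
            t = int(total[j])
            if best_mm is None or t < best_mm:
                best_mm = t
                best = [(contig, strand, int(q[j]), mism[j])]
            elif t == best_mm:
                best.append((contig, strand, int(q[j]), mism[j]))

    if best_mm is None:
        return Rejection(read.read_id, "unaligned")
    if params.unique_only and len(best) > 1:
        return Rejection(read.read_id, "multimapped")
    contig, strand, q, mism_row = best[0]
    n_real = index._strands[(contig, strand)].n_real
    start = q if strand == "+" else (n_real - q - rl) % n_real
    offsets = np.nonzero(mism_row)[0] - (rl - 1)
    return Alignment(read.read_id, contig, start, strand, rl, offsets)


def align_reads(
    reads: Iterable[ReadRecord],
    index: GenomeIndex,
    params: AlignParams | None = None,
) -> tuple[list[Alignment], list[Rejection]]:
    params = params or AlignParams()
    alignments, rejections = [], []
    for read in reads:
        result = align_read(read, index, params)
        if isinstance(result, Alignment):
            alignments.append(result)
        else:
            rejections.append(result)
    return alignments, rejections


# --- SAM serialisation (minimal dialect: ungapped, single-end) -------------


def write_sam(
    alignments: Sequence[Alignment],
    reads_by_id: dict[str, ReadRecord],
    genome: ReferenceGenome,
    path: str | Path,
) -> None:
    """One record per aligned read; SEQ/QUAL in reference-forward orientation."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name, seq in genome.contigs.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        for aln in alignments:
            read = reads_by_id[aln.read_id]
            if aln.strand == "+":
                flag, seq = 0, read.sequence
                qual = read.qualities
            else:
                flag, seq = 16, revcomp(read.sequence)
                qual = read.qualities[::-1]
            qual_str = "".join(chr(int(q) + 33) for q in qual)
            fh.write(
                f"{aln.read_id}\t{flag}\t{aln.contig}\t{aln.start + 1}\t255\t"
                f"{aln.read_length}M\t*\t0\t0\t{seq}\t{qual_str}\t"
                f"NM:i:{aln.n_mismatches}\n"
            )


def read_sam(
    path: str | Path, genome: ReferenceGenome
) -> tuple[list[Alignment], dict[str, ReadRecord]]:
    """Parse the minimal SAM dialect back into alignments and reads.

    Mismatch offsets are recomputed against the genome, so a round trip
    reproduces the original Alignment set exactly.
    """
    alignments: list[Alignment] = []
    reads: dict[str, ReadRecord] = {}
    enc = {name: encode(seq) for name, seq in genome.contigs.items()}
    with open(path) as fh:
        for line in fh:
            if line.startswith("@"):
                continue
            fields = line.rstrip("\n").split("\t")
            read_id, flag, contig, pos = fields[0], int(fields[1]), fields[2], int(fields[3])
            seq, qual_str = fields[9], fields[10]
            start = pos - 1
            rl = len(seq)
            quals = np.frombuffer(qual_str.encode(), dtype=np.uint8).astype(np.int64) - 33
            if flag & 16:
                strand = "-"
                tseq, tqual = revcomp(seq), quals[::-1]
            else:
                strand = "+"
                tseq, tqual = seq, quals
            read = ReadRecord(read_id, tseq, tqual)
            reads[read_id] = read
            ref = enc[contig]
            n = len(ref)
            if start + rl <= n:
                window = ref[start : start + rl]
            else:  # wrapped circular placement
                idx = (start + np.arange(rl)) % n
                window = ref[idx]
            if strand == "-":
                window = COMPLEMENT_CODE[window][::-1]
            offsets = np.nonzero(window != encode(tseq))[0] - (rl - 1)
            alignments.append(Alignment(read_id, contig, start, strand, rl, offsets))
    return alignments, reads
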