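"""Reference genome and annotation containers.

All internal coordinates are 0-based, half-open. Conversion to the 1-based
inclusive convention happens only at the GFF3/SAM/VCF serialisation boundary;
BED stays 0-based half-open.

"Transcript space" means sequence read 5'->3' along the RNA: for a
minus-strand feature that is the reverse complement of the forward genome
slice, with U written as T.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = "ACGT"
ALPHABET = "ACGTN"
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

# base codes: A=0 C=1 G=2 T=3 N=4
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(ALPHABET):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i
_DECODE = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)
N_CODE = 4

# code of the complementary base (N stays N)
COMPLEMENT_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


def complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)


def revcomp(seq: str) -> str:
    return complement(seq)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a base string to uint8 codes (A=0,C=1,G=2,T=3,N=4)."""
    return _ENCODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode()


@dataclass
class ReferenceGenome:
    """Named contigs of A/C/G/T/N with optional circularity.

    The single source of truth for all coordinates in the package.
    """

    contigs: dict[str, str]
    circular: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.contigs:
            self.circular.setdefault(name, False)

    @property
    def names(self) -> list[str]:
        return list(self.contigs)

    def length(self, contig: str) -> int:
        return len(self.contigs[contig])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.contigs.values())

    def fetch(self, contig: str, start: int, end: int) -> str:
        """Slice a contig, wrapping on circular contigs.

        On a linear contig, out-of-bounds positions are returned as ``N``
        placeholders so callers always receive ``end - start`` bases.
        """
        seq = self.contigs[contig]
        n = len(seq)
        if 0 <= start and end <= n:
            return seq[start:end]
        if self.circular.get(contig, False):
            return "".join(seq[i % n] for i in range(start, end))
        left = max(start, 0)
        right = min(end, n)
        core = seq[left:right] if left < right else ""
        return "N" * (left - start) + core + "N" * (end - right)

    def write_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="")
            for name, seq in self.contigs.items()
        ]
        with open(path, "w") as handle:
            SeqIO.write(records, handle, "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path, circular: dict[str, bool] | None = None) -> "ReferenceGenome":
        contigs = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
        }
        return cls(contigs, dict(circular or {}))


@dataclass(frozen=True, order=True)
class Interval:
    """0-based half-open genomic interval on one strand."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise ValueError(f"malformed interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, contig: str, position: int, strand: str | None = None) -> bool:
        if contig != self.contig:
            return False
        if strand is not None and strand != self.strand:
            return False
        return self.start <= position < self.end


@dataclass(frozen=True)
class Gene:
    """A simulated transcription unit: 5'UTR + CDS + 3'UTR on one strand.

    ``tx_start``/``tx_end`` bound the transcribed span; the CDS lies inside
    it. For minus-strand genes the 5' UTR sits at the high-coordinate end.
    """

    gene_id: str
    contig: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int

    @property
    def tx_length(self) -> int:
        return self.tx_end - self.tx_start


@dataclass
class AnnotationSet:
    """CDS / UTR / intron intervals, plus gene records when simulated."""

    cds: list[Interval] = field(default_factory=list)
    utr: list[Interval] = field(default_factory=list)
    introns: list[Interval] = field(default_factory=list)
    genes: list[Gene] = field(default_factory=list)

    @property
    def transcribed(self) -> list[Interval]:
        """Transcribed spans: gene spans when known, else CDS+UTR+introns."""
        if self.genes:
            return [
                Interval(g.contig, g.tx_start, g.tx_end, g.strand) for g in self.genes
            ]
        return self.cds + self.utr + self.introns

    def validate(self) -> None:
        """Reject same-strand overlap between CDS and UTR/intron intervals."""
        for a in self.cds:
            for b in self.utr + self.introns:
                if (
                    a.contig == b.contig
                    and a.strand == b.strand
                    and a.start < b.end
                    and b.start < a.end
                ):
                    raise ValueError(
                        f"CDS {a} overlaps untranslated interval {b} on the same strand"
                    )

    def write_gff3(self, path: str | Path) -> None:
        """CDS features, 1-based inclusive coordinates."""
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for i, iv in enumerate(self.cds):
                gene_id = (
                    self.genes[i].gene_id if i < len(self.genes) else f"cds{i:04d}"
                )
                fh.write(
                    f"{iv.contig}\tnetseq_fidelity\tCDS\t{iv.start + 1}\t{iv.end}\t."
                    f"\t{iv.strand}\t0\tID=cds-{gene_id};Parent={gene_id}\n"
                )

    def write_utr_bed(self, path: str | Path) -> None:
        intervals = [(iv, "utr") for iv in self.utr] + [
            (iv, "intron") for iv in self.introns
        ]
        write_bed(path, [iv for iv, _ in intervals], names=[n for _, n in intervals])


def write_bed(
    path: str | Path,
    intervals: Sequence[Interval],
    names: Sequence[str] | None = None,
) -> None:
    """6-column BED, 0-based half-open."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"iv{i:04d}"
            fh.write(f"{iv.contig}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_bed(path: str | Path) -> list[tuple[Interval, str]]:
    """Read a 3-6 column BED; returns (interval, name) pairs.

    Missing strand columns default to '+'; missing names to ''.
    """
    out: list[tuple[Interval, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has <3 columns")
            contig, start, end = fields[0], int(fields[1]), int(fields[2])
            name = fields[3] if len(fields) > 3 else ""
            strand = fields[5] if len(fields) > 5 and fields[5] in "+-" else "+"
            out.append((Interval(contig, start, end, strand), name))
    return out


def merge_intervals(pairs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge possibly-overlapping (start, end) half-open pairs."""
    pairs = sorted(pairs)
    merged: list[tuple[int, int]] = []
    for s, e in pairs:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def merged_length(intervals: Iterable[Interval]) -> int:
    """Total merged footprint, per (contig, strand) then summed.

    A position covered on both strands contributes twice: locations in this
    package are strand-resolved, so region lengths are too.
    """
    by_key: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for iv in intervals:
        by_key.setdefault((iv.contig, iv.strand), []).append((iv.start, iv.end))
    return sum(
        e - s for pairs in by_key.values() for s, e in merge_intervals(pairs)
    )
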