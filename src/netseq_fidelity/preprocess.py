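"""Read-level quality control before alignment.

Mirrors the pre-alignment filters used for NET-seq fidelity analysis:
3'-adapter trimming, minimum-length rejection, exclusion of reads carrying an
N at the position adjacent to the 3' terminus (a known systematic sequencing
artefact at that cycle), and post-alignment blacklist rejection of reads from
contaminant loci (tRNA/rRNA/snoRNA stand-ins).

Reads are stored 5'->3' in transcript space: the LAST base of the sequence
string is the nascent-RNA 3' terminus, so "offset from the 3' end" equals
offset from the end of the string.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genome import Interval

MAX_PHRED = 60


@dataclass
class ReadRecord:
    """One sequencing read: id, base string (5'->3'), per-base Phred scores."""

    read_id: str
    sequence: str
    qualities: np.ndarray

    def __post_init__(self) -> None:
        self.qualities = np.asarray(self.qualities, dtype=np.int64)
        if len(self.sequence) != len(self.qualities):
            raise ValueError(
                f"{self.read_id}: sequence length {len(self.sequence)} != "
                f"{len(self.qualities)} qualities"
            )
        if len(self.qualities) and (
            self.qualities.min() < 0 or self.qualities.max() > MAX_PHRED
        ):
            raise ValueError(f"{self.read_id}: Phred scores outside [0, {MAX_PHRED}]")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class FilterReport:
    """Tally of read fates through the pre-alignment filters."""

    n_input: int = 0
    n_trimmed: int = 0
    n_dropped_short: int = 0
    n_dropped_n_3prime_adjacent: int = 0
    n_dropped_blacklist: int = 0
    n_surviving: int = 0

    def validate(self) -> None:
        dropped = (
            self.n_dropped_short
            + self.n_dropped_n_3prime_adjacent
            + self.n_dropped_blacklist
        )
        if self.n_input != self.n_surviving + dropped:
            raise ValueError("filter report does not conserve reads")

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def trim_adapter(read: ReadRecord, adapter: str, min_overlap: int = 3) -> ReadRecord:
    """Remove the longest read suffix exactly matching a prefix of the adapter.

    Matches of length < ``min_overlap`` are ignored; with no match the read
    is returned unchanged.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    seq = read.sequence
    kmax = min(len(seq), len(adapter))
    for k in range(kmax, min_overlap - 1, -1):
        if seq.endswith(adapter[:k]):
            return replace(
                read, sequence=seq[: len(seq) - k], qualities=read.qualities[: len(seq) - k]
            )
    return read


def filter_reads(
    reads: Iterable[ReadRecord],
    min_length: int = 16,
    drop_n_at_3prime_adjacent: bool = True,
    adapter: str | None = None,
    min_overlap: int = 3,
) -> tuple[list[ReadRecord], FilterReport]:
    """Apply pre-alignment filters; returns surviving reads and a tally.

    The "3'-adjacent" position is the read base immediately upstream (-1)
    of the 3' terminal base, i.e. the penultimate character of the
    transcript-space read string.

    Blacklist (contaminant-locus) rejection happens after alignment, via
    :func:`apply_blacklist`, because it needs genomic coordinates; its count
    is folded into the same report there.
    """
    kept: list[ReadRecord] = []
    report = FilterReport()
    for read in reads:
        report.n_input += 1
        if adapter is not None:
            trimmed = trim_adapter(read, adapter, min_overlap)
            if len(trimmed) < len(read):
                report.n_trimmed += 1
            read = trimmed
        if len(read) < min_length:
            report.n_dropped_short += 1
            continue
        if (
            drop_n_at_3prime_adjacent
            and len(read) >= 2
            and read.sequence[-2] == "N"
        ):
            report.n_dropped_n_3prime_adjacent += 1
            continue
        kept.append(read)
        report.n_surviving += 1
    report.validate()
    return kept, report


def apply_blacklist(
    alignments: Sequence,
    blacklist: Sequence[Interval],
    report: FilterReport | None = None,
):
    """Drop alignments overlapping any blacklist interval (strand-agnostic).

    Returns the kept alignments; updates ``report`` counts in place when
    given (reads removed here move from surviving to dropped-blacklist).
    """
    if not blacklist:
        return list(alignments)
    by_contig: dict[str, list[tuple[int, int]]] = {}
    for iv in blacklist:
        by_contig.setdefault(iv.contig, []).append((iv.start, iv.end))
    kept = []
    n_dropped = 0
    for aln in alignments:
        hit = any(
            aln.start < e and s < aln.start + aln.read_length
            for s, e in by_contig.get(aln.contig, ())
        )
        if hit:
            n_dropped += 1
        else:
            kept.append(aln)
    if report is not None:
        report.n_dropped_blacklist += n_dropped
        report.n_surviving -= n_dropped
        report.validate()
    return kept


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    """Sanger FASTQ (Phred+33)."""
    records = []
    for read in reads:
        rec = SeqRecord(Seq(read.sequence), id=read.read_id, description="")
        rec.letter_annotations["phred_quality"] = [int(q) for q in read.qualities]
        records.append(rec)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fastq")


def read_fastq(path: str | Path) -> list[ReadRecord]:
    return [
        ReadRecord(
            rec.id,
            str(rec.seq).upper(),
            np.asarray(rec.letter_annotations["phred_quality"], dtype=np.int64),
        )
        for rec in SeqIO.parse(str(path), "fastq")
    ]
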