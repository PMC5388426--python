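"""Independent brute-force oracles used to cross-check the implementation.

These deliberately share no code with the package: the aligner oracle scores
every placement on both strands by direct string comparison, and the rate
oracle recounts mismatches with nested Python loops.
"""

from __future__ import annotations

from collections import Counter

COMPL = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPL)[::-1]


def _mismatches(a: str, b: str) -> list[int]:
    return [i for i, (x, y) in enumerate(zip(a, b)) if x != y or x == "N" or y == "N"]


def exhaustive_align(
    read_seq: str,
    contigs: dict[str, str],
    seed_len: int = 14,
    seed_mismatches: int = 2,
    unique_only: bool = True,
    circular: dict[str, bool] | None = None,
):
    """Score every ungapped placement of the read on both strands.

    Returns ("aligned", contig, strand, start, n_mismatches) or
    ("too_short"|"unaligned"|"multimapped",).
    The seed is the last ``seed_len`` bases of the transcript-space read.
    """
    rl = len(read_seq)
    if rl < seed_len:
        return ("too_short",)
    circular = circular or {}
    candidates = []  # (total_mm, contig, strand, forward_start)
    for contig, seq in contigs.items():
        n = len(seq)
        for strand in "+-":
            strand_seq = seq if strand == "+" else revcomp(seq)
            if circular.get(contig, False):
                strand_seq = strand_seq + strand_seq[: rl - 1]
                limit = n
            else:
                limit = n - rl + 1
            for q in range(max(limit, 0)):
                window = strand_seq[q : q + rl]
                mm = _mismatches(window, read_seq)
                seed_mm = sum(1 for i in mm if i >= rl - seed_len)
                if seed_mm <= seed_mismatches:
                    start = q if strand == "+" else (n - q - rl) % n
                    candidates.append((len(mm), contig, strand, start))
    if not candidates:
        return ("unaligned",)
    best_mm = min(c[0] for c in candidates)
    best = [c for c in candidates if c[0] == best_mm]
    if unique_only and len(best) > 1:
        return ("multimapped",)
    mm, contig, strand, start = best[0]
    return ("aligned", contig, strand, start, mm)


def naive_error_table(
    alignments,
    reads_by_id,
    contigs: dict[str, str],
    variant_positions: set | None = None,
    phred_min: int = 30,
    window: int = 11,
):
    """Recount denominators and per-offset mismatch/substitution tallies."""
    variant_positions = variant_positions or set()
    denominators = [0] * window
    mismatches = [0] * window
    specific: list[Counter] = [Counter() for _ in range(window)]
    for aln in alignments:
        read = reads_by_id[aln.read_id]
        seq = read.sequence
        rl = len(seq)
        ref = contigs[aln.contig]
        for k in range(min(window, rl)):
            i = rl - 1 - k  # read index at offset -k
            read_base = seq[i]
            if aln.strand == "+":
                pos = aln.start + i
                tmpl = ref[pos % len(ref)]
            else:
                pos = aln.start + (rl - 1 - i)
                tmpl = revcomp(ref[pos % len(ref)])
            if read_base != "N":
                denominators[k] += 1
            if (
                read_base != tmpl
                and read_base != "N"
                and tmpl != "N"
                and read.qualities[i] >= phred_min
                and (aln.contig, pos % len(ref)) not in variant_positions
            ):
                mismatches[k] += 1
                specific[k][f"{tmpl}>{read_base}"] += 1
    return denominators, mismatches, specific


def naive_pileup(alignments, reads_by_id, contigs: dict[str, str]):
    """(contig, position) -> Counter of forward-strand base identities."""
    columns: dict[tuple[str, int], Counter] = {}
    for aln in alignments:
        read = reads_by_id[aln.read_id]
        rl = len(read.sequence)
        n = len(contigs[aln.contig])
        for i, base in enumerate(read.sequence):
            if aln.strand == "+":
                pos = (aln.start + i) % n
                fwd = base
            else:
                pos = (aln.start + (rl - 1 - i)) % n
                fwd = base.translate(COMPL)
            columns.setdefault((aln.contig, pos), Counter())[fwd] += 1
    return columns
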