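"""Synthetic NET-seq data generator with recorded ground truth.

Emulates the statistical structure of a NET-seq fidelity experiment:

* a random genome carrying non-overlapping genes (5'UTR + CDS + 3'UTR) on
  both strands;
* a population of elongation complexes (ECs) whose nascent-RNA 3' ends fall
  inside transcribed spans, sampled with per-gene abundance weights;
* short 3'-anchored reads (the last base of each read string is the nascent
  3' terminus) with a configurable fraction of ECs carrying a 3'-terminal
  misincorporation drawn from a 12-class substitution spectrum, optional
  motif-dependent hotspot enrichment (C at -1, G at the misincorporated
  position), and low-rate U>C read-through errors at offsets -1/-2;
* an experimental error layer: reverse-transcription, PCR (folded into a
  single per-base Bernoulli with p = cycles x per-cycle rate) and sequencing
  miscalls, the latter with a distinct, lower Phred-quality model so that a
  quality threshold separates them from biological events.

Every injected event is recorded in a per-read :class:`TruthRecord` so
recovery can be audited exactly. RNA bases are stored in the DNA alphabet
(U written as T).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .genome import (
    AnnotationSet,
    COMPLEMENT_CODE,
    Gene,
    Interval,
    ReferenceGenome,
    decode,
    encode,
)
from .preprocess import ReadRecord

#: shortest seed the aligner uses; reads must not be shorter
MIN_READ_FOR_SEED = 14

SUBSTITUTIONS = tuple(
    f"{t}>{r}" for t in "ACGT" for r in "ACGT" if t != r
)  # 12 classes, template>read in transcript space

#: G>A-dominant substitution spectrum: misincorporation of AMP is the most
#: frequent error regardless of template base, with G>A far ahead. An EC's
#: misincorporation flag is drawn independently of its template base; the
#: substitution class is then sampled from this spectrum restricted to the
#: template's row, so the realised class mix is the row-conditional spectrum
#: weighted by template-base availability at EC 3' ends. The weights below
#: keep G>A clearly modal after that reweighting on a ~50% GC genome.
DEFAULT_SPECTRUM: dict[str, float] = {
    "G>A": 0.50,
    "C>A": 0.10,
    "T>A": 0.10,
    "A>G": 0.05,
    "A>C": 0.03,
    "A>T": 0.03,
    "C>G": 0.03,
    "C>T": 0.04,
    "G>C": 0.03,
    "G>T": 0.03,
    "T>C": 0.04,
    "T>G": 0.02,
}

_BASE_CODE = {b: i for i, b in enumerate("ACGT")}


@dataclass
class QualityModel:
    """Phred-score model: correct bases vs sequencing miscalls.

    Both are normal draws truncated to [q_min, q_max] and rounded; miscalled
    bases score lower on average, so a Phred >=30 filter removes most of
    them while keeping genuine (pre-sequencing) mismatches.
    """

    correct_mean: float = 38.0
    correct_sd: float = 2.0
    error_mean: float = 22.0
    error_sd: float = 6.0
    q_min: int = 2
    q_max: int = 40


@dataclass
class SimConfig:
    """Parameters of one synthetic NET-seq experiment."""

    genome_length: int = 200_000
    gc_fraction: float = 0.5
    n_genes: int = 40
    utr5_len: int = 50
    utr3_len: int = 100
    cds_len_min: int = 300
    cds_len_max: int = 1500
    n_ecs: int = 200_000
    misinc_fraction: float = 0.03
    substitution_spectrum: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPECTRUM)
    )
    hotspot_motif_boost: float = 1.0
    readthrough_rate: float = 0.0
    read_length_min: int = 16
    read_length_max: int = 30
    variant_positions: int = 0
    rt_error_rate: float = 1e-4
    pcr_error_rate: float = 4e-7
    pcr_cycles: int = 15
    seq_error_rate: float = 1e-3
    quality_model: QualityModel = field(default_factory=QualityModel)
    gene_weights: Sequence[float] | None = None
    abundance_lognormal_sigma: float = 1.0
    seed: int = 12345

    def validate(self) -> None:
        total = sum(self.substitution_spectrum.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"substitution spectrum sums to {total}, not 1")
        if set(self.substitution_spectrum) - set(SUBSTITUTIONS):
            raise ValueError("unknown substitution labels in spectrum")
        for name in (
            "gc_fraction",
            "misinc_fraction",
            "readthrough_rate",
            "rt_error_rate",
            "pcr_error_rate",
            "seq_error_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.read_length_min < MIN_READ_FOR_SEED:
            raise ValueError(
                f"read_length_min must be >= aligner seed length {MIN_READ_FOR_SEED}"
            )
        if self.read_length_min > self.read_length_max:
            raise ValueError("read_length_min > read_length_max")
        if self.hotspot_motif_boost < 0:
            raise ValueError("hotspot_motif_boost must be >= 0")


class EC(NamedTuple):
    """An elongation complex: where the nascent RNA 3' end sits."""

    contig: str
    strand: str
    position: int  # genomic (forward) coordinate of the 3' terminus, 0-based


class InjectedEvent(NamedTuple):
    offset: int  # 0, -1, ... from the 3' end
    template_base: str  # base the layer saw at that position (transcript space)
    read_base: str  # base after the layer acted
    layer: str  # misincorporation | readthrough | rt | pcr | sequencing


@dataclass
class TruthRecord:
    """Ground truth for one emitted read."""

    read_id: str
    contig: str
    strand: str
    genomic_3prime_position: int
    injected_events: list[InjectedEvent] = field(default_factory=list)
    is_misincorporated_ec: bool = False

    def validate(self) -> None:
        for ev in self.injected_events:
            if ev.offset > 0:
                raise ValueError("event offsets must be <= 0")
            if ev.layer == "misincorporation" and ev.offset != 0:
                raise ValueError("misincorporation only at offset 0")
            if ev.layer == "readthrough" and ev.offset not in (-1, -2):
                raise ValueError("readthrough only at offsets -1/-2")


class PlantedVariant(NamedTuple):
    contig: str
    position: int  # 0-based, forward strand
    ref: str
    alt: str


def generate_genome(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[ReferenceGenome, AnnotationSet]:
    """Random genome plus non-overlapping genes on both strands.

    Gene footprints (5'UTR + CDS + 3'UTR, CDS length divisible by 3) are
    placed with random inter-gene gaps; fails if they cannot fit.
    Deterministic given ``config.seed`` (or the supplied generator).
    """
    config.validate()
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    gc = config.gc_fraction
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    codes = rng.choice(4, size=config.genome_length, p=probs).astype(np.uint8)
    contig = "contig_1"
    genome = ReferenceGenome({contig: decode(codes)})

    annotation = AnnotationSet()
    n = config.n_genes
    if n == 0:
        return genome, annotation

    cds_lens = 3 * rng.integers(
        config.cds_len_min // 3, config.cds_len_max // 3 + 1, size=n
    )
    footprints = config.utr5_len + cds_lens + config.utr3_len
    slack = config.genome_length - int(footprints.sum())
    if slack < 0:
        raise ValueError(
            f"cannot place {n} genes without overlap: need {footprints.sum()} bases "
            f"in a {config.genome_length}-base genome"
        )
    gaps = rng.multinomial(slack, [1.0 / (n + 1)] * (n + 1))
    strands = rng.choice(np.array(["+", "-"]), size=n)

    cursor = 0
    for i in range(n):
        cursor += int(gaps[i])
        s, e = cursor, cursor + int(footprints[i])
        u5, u3, cl = config.utr5_len, config.utr3_len, int(cds_lens[i])
        strand = str(strands[i])
        if strand == "+":
            utr5 = Interval(contig, s, s + u5, "+")
            cds = Interval(contig, s + u5, s + u5 + cl, "+")
            utr3 = Interval(contig, s + u5 + cl, e, "+")
        else:
            utr3 = Interval(contig, s, s + u3, "-")
            cds = Interval(contig, s + u3, s + u3 + cl, "-")
            utr5 = Interval(contig, s + u3 + cl, e, "-")
        gene = Gene(f"gene{i:04d}", contig, strand, s, e, cds.start, cds.end)
        annotation.genes.append(gene)
        annotation.cds.append(cds)
        annotation.utr.extend([utr5, utr3])
        cursor = e
    annotation.validate()
    return genome, annotation


def plant_variants(
    genome: ReferenceGenome,
    annotation: AnnotationSet,
    n_variants: int,
    rng: np.random.Generator,
) -> tuple[ReferenceGenome, list[PlantedVariant]]:
    """Plant homozygous strain-vs-reference substitutions inside genes.

    Returns the strain genome (reads are synthesised from it) and the list
    of planted variants; the original reference is left untouched. Positions
    are restricted to transcribed spans so they receive read coverage.
    """
    if n_variants == 0:
        return genome, []
    spans = annotation.transcribed
    if not spans:
        raise ValueError("cannot plant variants without transcribed intervals")
    candidates = np.concatenate([np.arange(iv.start, iv.end) for iv in spans])
    candidates = np.unique(candidates)
    if len(candidates) < n_variants:
        raise ValueError("not enough transcribed positions for requested variants")
    positions = np.sort(rng.choice(candidates, size=n_variants, replace=False))
    contig = spans[0].contig
    strain = bytearray(genome.contigs[contig], "ascii")
    variants = []
    for pos in positions:
        ref = chr(strain[pos])
        alt = "ACGT".replace(ref, "")[rng.integers(0, 3)]
        strain[pos] = ord(alt)
        variants.append(PlantedVariant(contig, int(pos), ref, alt))
    strain_genome = ReferenceGenome(
        {**genome.contigs, contig: strain.decode()}, dict(genome.circular)
    )
    return strain_genome, variants


def sample_elongation_complexes(
    genome: ReferenceGenome,
    annotation: AnnotationSet,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    weights: Sequence[float] | None = None,
) -> list[EC]:
    """Place EC 3' ends inside transcribed spans with per-gene abundances.

    Each 3' position lies at least ``read_length_max - 1`` bases downstream
    of the transcript start, so a full-length read always fits inside the
    transcript.
    """
    config.validate()
    if not annotation.genes:
        raise ValueError("annotation has no genes to transcribe")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lmax = config.read_length_max

    spans: list[tuple[Gene, int, int]] = []  # gene, eligible lo, span size
    for gene in annotation.genes:
        size = gene.tx_length - lmax + 1
        if size <= 0:
            spans.append((gene, 0, 0))
            continue
        lo = gene.tx_start + lmax - 1 if gene.strand == "+" else gene.tx_start
        spans.append((gene, lo, size))

    if weights is None:
        weights = config.gene_weights
    if weights is None:
        weights = rng.lognormal(0.0, config.abundance_lognormal_sigma, len(annotation.genes))
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(annotation.genes):
        raise ValueError("one abundance weight per gene required")
    weights = np.where([s == 0 for _, _, s in spans], 0.0, weights)
    if weights.sum() <= 0:
        raise ValueError("no transcript long enough to carry a full read")
    probs = weights / weights.sum()

    counts = rng.multinomial(config.n_ecs, probs)
    ecs: list[EC] = []
    for (gene, lo, size), k in zip(spans, counts):
        if k == 0:
            continue
        positions = lo + rng.integers(0, size, size=int(k))
        ecs.extend(
            EC(gene.contig, gene.strand, int(p)) for p in np.sort(positions)
        )
    return ecs


def _conditional_spectrum(spectrum: dict[str, float]) -> list[list[tuple[int, float]]]:
    """Per-template-base renormalised substitution choices."""
    cond: list[list[tuple[int, float]]] = []
    for t in "ACGT":
        entries = [
            (_BASE_CODE[lab[2]], p)
            for lab, p in spectrum.items()
            if lab[0] == t and p > 0
        ]
        total = sum(p for _, p in entries)
        cond.append([(c, p / total) for c, p in entries] if total > 0 else [])
    return cond


def synthesize_reads(
    ecs: Sequence[EC],
    genome: ReferenceGenome,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[ReadRecord], list[TruthRecord]]:
    """Emit transcript-space reads ending at each EC's 3' position.

    ``genome`` is the template the polymerase copied — pass the strain
    genome when variants were planted. Layer order: misincorporation,
    read-through, RT, PCR, sequencing; Phred strings follow the quality
    model, with sequencing miscalls drawn from the low-quality component.
    """
    config.validate()
    if not ecs:
        raise ValueError("empty elongation-complex list")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = len(ecs)
    qm = config.quality_model

    enc = {name: encode(seq) for name, seq in genome.contigs.items()}
    cond = _conditional_spectrum(config.substitution_spectrum)

    lengths = rng.integers(config.read_length_min, config.read_length_max + 1, size=n)
    u_mis = rng.random(n)
    u_sub = rng.random(n)
    u_rt1 = rng.random(n)
    u_rt2 = rng.random(n)

    layer_rates = (
        ("rt", config.rt_error_rate),
        ("pcr", min(1.0, config.pcr_cycles * config.pcr_error_rate)),
        ("sequencing", config.seq_error_rate),
    )
    layer_counts = {
        name: rng.binomial(lengths, rate) if rate > 0 else np.zeros(n, dtype=np.int64)
        for name, rate in layer_rates
    }

    starts = np.zeros(n + 1, dtype=np.int64)
    np.cumsum(lengths, out=starts[1:])
    total_bases = int(starts[-1])
    all_qual = np.clip(
        np.rint(rng.normal(qm.correct_mean, qm.correct_sd, total_bases)),
        qm.q_min,
        qm.q_max,
    ).astype(np.int64)

    p_mis = config.misinc_fraction
    p_mis_hot = min(1.0, p_mis * config.hotspot_motif_boost)
    rt_rate = config.readthrough_rate

    reads: list[ReadRecord] = []
    truth: list[TruthRecord] = []
    base_chr = "ACGTN"

    for i, ec in enumerate(ecs):
        L = int(lengths[i])
        arr = enc[ec.contig]
        if ec.strand == "+":
            tmpl = arr[ec.position - L + 1 : ec.position + 1].copy()
        else:
            tmpl = COMPLEMENT_CODE[arr[ec.position : ec.position + L]][::-1].copy()
        codes = tmpl.copy()
        events: list[InjectedEvent] = []

        # biological layer: 3'-terminal misincorporation
        motif = L >= 2 and tmpl[-1] == 2 and tmpl[-2] == 1  # G at 0, C at -1
        p = p_mis_hot if motif else p_mis
        misincorporated = bool(u_mis[i] < p)
        if misincorporated:
            choices = cond[tmpl[-1]] if tmpl[-1] < 4 else []
            if choices:
                u, acc = u_sub[i], 0.0
                new = choices[-1][0]
                for code, pr in choices:
                    acc += pr
                    if u < acc:
                        new = code
                        break
                events.append(
                    InjectedEvent(0, base_chr[tmpl[-1]], base_chr[new], "misincorporation")
                )
                codes[-1] = new

        # biological layer: U>C read-through at -1 / -2
        if rt_rate > 0:
            for off, u in ((-1, u_rt1[i]), (-2, u_rt2[i])):
                idx = L - 1 + off
                if idx >= 0 and codes[idx] == 3 and u < rt_rate:
                    events.append(InjectedEvent(off, "T", "C", "readthrough"))
                    codes[idx] = 1

        # experimental layers: RT, PCR, sequencing miscalls
        seq_error_idx: list[int] = []
        for layer, _rate in layer_rates:
            k = int(layer_counts[layer][i])
            if k == 0:
                continue
            positions = rng.choice(L, size=min(k, L), replace=False)
            shifts = rng.integers(1, 4, size=len(positions))
            for j, sh in zip(positions, shifts):
                before = int(codes[j])
                if before >= 4:
                    continue
                after = (before + int(sh)) % 4
                events.append(
                    InjectedEvent(
                        int(j) - (L - 1), base_chr[before], base_chr[after], layer
                    )
                )
                codes[j] = after
                if layer == "sequencing":
                    seq_error_idx.append(int(j))

        qual = all_qual[starts[i] : starts[i + 1]]
        if seq_error_idx:
            qual = qual.copy()
            draws = np.clip(
                np.rint(rng.normal(qm.error_mean, qm.error_sd, len(seq_error_idx))),
                qm.q_min,
                qm.q_max,
            ).astype(np.int64)
            qual[seq_error_idx] = draws

        read_id = f"read{i:07d}"
        reads.append(ReadRecord(read_id, decode(codes), qual))
        rec = TruthRecord(
            read_id, ec.contig, ec.strand, ec.position, events, misincorporated
        )
        rec.validate()
        truth.append(rec)

    return reads, truth


@dataclass
class SimulationBundle:
    """Everything one synthetic run produced, ground truth included."""

    config: SimConfig
    reference: ReferenceGenome
    annotation: AnnotationSet
    strain: ReferenceGenome
    variants: list[PlantedVariant]
    ecs: list[EC]
    reads: list[ReadRecord]
    truth: list[TruthRecord]


def simulate(
    config: SimConfig, rng: np.random.Generator | None = None
) -> SimulationBundle:
    """Full generation pass: genome, variants, ECs, reads, truth.

    Uses independent substreams of one seed so each stage is reproducible.
    """
    config.validate()
    if rng is None:
        streams = np.random.SeedSequence(config.seed).spawn(4)
    else:
        streams = rng.bit_generator.seed_seq.spawn(4)  # type: ignore[union-attr]
    rng_genome, rng_var, rng_ec, rng_read = map(np.random.default_rng, streams)

    reference, annotation = generate_genome(config, rng_genome)
    strain, variants = plant_variants(
        reference, annotation, config.variant_positions, rng_var
    )
    ecs = sample_elongation_complexes(reference, annotation, config, rng_ec)
    reads, truth = synthesize_reads(ecs, strain, config, rng_read)
    return SimulationBundle(
        config, reference, annotation, strain, variants, ecs, reads, truth
    )


TRUTH_COLUMNS = (
    "read_id",
    "contig",
    "strand",
    "pos3",
    "offset",
    "tmpl",
    "obs",
    "layer",
    "misinc_ec",
)


def truth_table_frame(truth: Sequence[TruthRecord]) -> pd.DataFrame:
    """One row per injected event; event-free reads get a 'none' row."""
    rows = []
    for rec in truth:
        flag = int(rec.is_misincorporated_ec)
        if rec.injected_events:
            for ev in rec.injected_events:
                rows.append(
                    (
                        rec.read_id,
                        rec.contig,
                        rec.strand,
                        rec.genomic_3prime_position,
                        ev.offset,
                        ev.template_base,
                        ev.read_base,
                        ev.layer,
                        flag,
                    )
                )
        else:
            rows.append(
                (
                    rec.read_id,
                    rec.contig,
                    rec.strand,
                    rec.genomic_3prime_position,
                    0,
                    ".",
                    ".",
                    "none",
                    flag,
                )
            )
    return pd.DataFrame(rows, columns=TRUTH_COLUMNS)


def write_truth_table(truth: Sequence[TruthRecord], path: str | Path) -> None:
    truth_table_frame(truth).to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"tmpl": str, "obs": str})
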