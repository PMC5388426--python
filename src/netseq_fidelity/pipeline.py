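"""End-to-end orchestration: simulate -> preprocess -> align -> mask ->
spectrum -> context -> regions -> accuracy, with one seed and one report.

Every stage logs its input/output record counts; identical config + seed
reproduces byte-identical artifacts. When an output directory is given, all
intermediate artifacts are persisted (FASTA/GFF3/BED/FASTQ/SAM/VCF/TSV) and
stages can be toggled off to consume artifacts from a prior run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
import yaml

from . import accuracy as accuracy_mod
from . import context as context_mod
from . import regions as regions_mod
from . import spectrum as spectrum_mod
from . import varmask as varmask_mod
from ._stacking import stack_alignments
from .align import AlignParams, GenomeIndex, align_reads, write_sam
from .genome import Interval, ReferenceGenome
from .preprocess import apply_blacklist, filter_reads, read_fastq, write_fastq
from .simulate import (
    SimConfig,
    SimulationBundle,
    TruthRecord,
    simulate,
    read_truth_table,
    truth_table_frame,
    write_truth_table,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    align: AlignParams = field(default_factory=AlignParams)
    budget: accuracy_mod.ErrorBudget = field(default_factory=accuracy_mod.ErrorBudget)
    min_read_length: int = 16
    drop_n_at_3prime_adjacent: bool = True
    adapter: str | None = None
    blacklist: list[Interval] = field(default_factory=list)
    min_depth: int = 10
    min_alt_fraction: float = 0.8
    phred_min: int = 30
    window: int = 11
    quality_in_denominator: bool = False
    hotspot_min_count: int = 50
    hotspot_substitution: str = "G>A"
    halfwidth: int = 5
    region_mode: str = "bacteria"
    seed: int | None = None  # overrides sim.seed when set
    output_dir: str | Path | None = None
    run_simulate: bool = True
    run_varmask: bool = True
    run_context: bool = True
    run_regions: bool = True
    run_accuracy: bool = True
    compare_truth: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "sim" in kwargs:
            sim = dict(kwargs["sim"])
            if "quality_model" in sim:
                from .simulate import QualityModel

                sim["quality_model"] = QualityModel(**sim["quality_model"])
            kwargs["sim"] = SimConfig(**sim)
        if "align" in kwargs:
            kwargs["align"] = AlignParams(**kwargs["align"])
        if "budget" in kwargs:
            kwargs["budget"] = accuracy_mod.ErrorBudget(**kwargs["budget"])
        if "blacklist" in kwargs:
            kwargs["blacklist"] = [
                Interval(**iv) if isinstance(iv, dict) else iv
                for iv in kwargs["blacklist"]
            ]
        return cls(**kwargs)


@dataclass
class RunReport:
    """Consolidated outputs of one pipeline run."""

    config_seed: int
    filter_report: dict
    alignment_summary: dict
    variant_count: int | None = None
    error_table: spectrum_mod.PositionalErrorTable | None = None
    misincorporated_ec_percent: float | None = None
    sweep: pd.DataFrame | None = None
    hotspots: list = field(default_factory=list)
    pfm: context_mod.PositionFrequencyMatrix | None = None
    region_table: pd.DataFrame | None = None
    accuracy: list | None = None
    truth_comparison: dict | None = None

    def to_dict(self) -> dict:
        out: dict[str, Any] = {
            "config_seed": self.config_seed,
            "filter_report": self.filter_report,
            "alignment_summary": self.alignment_summary,
            "variant_count": self.variant_count,
            "misincorporated_ec_percent": self.misincorporated_ec_percent,
            "truth_comparison": self.truth_comparison,
        }
        if self.error_table is not None:
            out["positional_error_table"] = self.error_table.to_dict()
        if self.sweep is not None:
            out["threshold_sweep"] = self.sweep.to_dict(orient="records")
        if self.hotspots:
            out["hotspots"] = [dataclasses.asdict(h) for h in self.hotspots]
        else:
            out["hotspots"] = []
        if self.pfm is not None:
            out["pfm"] = {
                "n_sequences": self.pfm.n_sequences,
                "frequencies": np.where(
                    np.isnan(self.pfm.frequencies), None, self.pfm.frequencies
                ).tolist(),
            }
        if self.region_table is not None:
            out["region_table"] = (
                self.region_table.replace({np.nan: None}).reset_index().to_dict(orient="records")
            )
        if self.accuracy is not None:
            out["accuracy"] = self.accuracy
        return _jsonify(out)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def run(config: PipelineConfig) -> RunReport:
    """Execute the pipeline stages in order; see module docstring."""
    if config.seed is not None:
        config.sim = dataclasses.replace(config.sim, seed=config.seed)
    out_dir = Path(config.output_dir) if config.output_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    # --- simulate (or resume from persisted artifacts) ---
    if config.run_simulate:
        bundle = simulate(config.sim)
        logger.info("simulated %d reads over %d genes", len(bundle.reads), len(bundle.annotation.genes))
        if out_dir is not None:
            bundle.reference.write_fasta(out_dir / "reference.fasta")
            bundle.annotation.write_gff3(out_dir / "annotation.gff3")
            bundle.annotation.write_utr_bed(out_dir / "utr.bed")
            write_fastq(bundle.reads, out_dir / "reads.fastq")
            write_truth_table(bundle.truth, out_dir / "truth.tsv")
        reference, annotation = bundle.reference, bundle.annotation
        reads, truth = bundle.reads, bundle.truth
    else:
        if out_dir is None:
            raise ValueError("resuming without simulate requires output_dir artifacts")
        reference = ReferenceGenome.from_fasta(out_dir / "reference.fasta")
        annotation = regions_mod.load_annotation(
            out_dir / "annotation.gff3", out_dir / "utr.bed",
            mode="yeast" if config.region_mode == "yeast" else "bacteria",
        )
        reads = read_fastq(out_dir / "reads.fastq")
        truth_path = out_dir / "truth.tsv"
        truth = read_truth_table(truth_path) if truth_path.exists() else None
        logger.info("resumed %d reads from %s", len(reads), out_dir)

    # --- preprocess ---
    kept, filter_report = filter_reads(
        reads,
        min_length=config.min_read_length,
        drop_n_at_3prime_adjacent=config.drop_n_at_3prime_adjacent,
        adapter=config.adapter,
    )
    logger.info("preprocess: %d of %d reads survive", filter_report.n_surviving, filter_report.n_input)

    # --- align ---
    index = GenomeIndex(reference, config.align.seed_len)
    alignments, rejections = align_reads(kept, index, config.align)
    n_reject = {"too_short": 0, "unaligned": 0, "multimapped": 0}
    for rej in rejections:
        n_reject[rej.reason] += 1
    alignments = apply_blacklist(alignments, config.blacklist, filter_report)
    summary = {
        "n_aligned": len(alignments),
        "n_multimapped": n_reject["multimapped"],
        "n_unaligned": n_reject["unaligned"],
        "n_too_short": n_reject["too_short"],
        "n_blacklisted": filter_report.n_dropped_blacklist,
    }
    logger.info("align: %s", summary)
    reads_by_id = {r.read_id: r for r in kept}
    if out_dir is not None:
        write_sam(alignments, reads_by_id, reference, out_dir / "alignments.sam")

    report = RunReport(
        config_seed=config.sim.seed,
        filter_report=filter_report.to_dict(),
        alignment_summary=summary,
    )

    stacked = stack_alignments(alignments, reads_by_id, reference)

    # --- variant calling and masking ---
    variants = varmask_mod.VariantSet([])
    if config.run_varmask:
        columns = varmask_mod.pileup(alignments, reads_by_id, reference, stacked=stacked)
        variants = varmask_mod.call_variants(
            columns, reference, config.min_depth, config.min_alt_fraction
        )
        report.variant_count = len(variants)
        logger.info("varmask: %d variants called", len(variants))
        if out_dir is not None:
            varmask_mod.write_vcf(variants, out_dir / "variants.vcf")

    # --- spectrum ---
    events, denominators = spectrum_mod.extract_mismatch_events(
        alignments,
        reads_by_id,
        reference,
        variants=variants,
        phred_min=config.phred_min,
        window=config.window,
        quality_in_denominator=config.quality_in_denominator,
        stacked=stacked,
    )
    table = spectrum_mod.positional_error_table(events, denominators)
    report.error_table = table
    if denominators[0] > 0:
        report.misincorporated_ec_percent = spectrum_mod.misincorporated_ec_fraction(table)
    report.sweep = spectrum_mod.threshold_sweep(events)
    logger.info("spectrum: %d events over %d offsets", len(events), config.window)
    if out_dir is not None:
        spectrum_mod.write_events(events, out_dir / "events.tsv")
        table.to_frame().to_csv(out_dir / "error_table.tsv", sep="\t", index=False)
        report.sweep.to_csv(out_dir / "threshold_sweep.tsv", sep="\t", index=False)

    # --- context / hotspots ---
    if config.run_context:
        hotspots = context_mod.call_hotspots(
            events,
            reference,
            substitution=config.hotspot_substitution,
            min_count=config.hotspot_min_count,
            halfwidth=config.halfwidth,
        )
        report.hotspots = hotspots
        contexts = context_mod.hotspot_contexts(hotspots)
        if contexts:
            report.pfm = context_mod.position_frequency_matrix(contexts)
        logger.info("context: %d hotspots", len(hotspots))
        if out_dir is not None:
            context_mod.hotspots_frame(hotspots).to_csv(
                out_dir / "hotspots.tsv", sep="\t", index=False
            )
            context_mod.write_hotspots_bed(hotspots, out_dir / "hotspots.bed")
            if report.pfm is not None:
                report.pfm.to_frame().to_csv(out_dir / "pfm.tsv", sep="\t")

    # --- regions ---
    if config.run_regions:
        report.region_table = regions_mod.region_rate_table(
            events, report.hotspots, annotation, reference, mode=config.region_mode
        )
        if out_dir is not None:
            report.region_table.to_csv(out_dir / "region_table.tsv", sep="\t")

    # --- accuracy ---
    if config.run_accuracy:
        report.accuracy = accuracy_mod.accuracy_report(
            table.total_rate_percent, config.budget
        )

    # --- truth comparison (synthetic runs only) ---
    if config.compare_truth and truth is not None:
        report.truth_comparison = compare_to_truth(
            report, truth, min_count=config.hotspot_min_count
        )

    if out_dir is not None:
        with open(out_dir / "report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=2)
    return report


def compare_to_truth(
    report: RunReport,
    truth: Sequence[TruthRecord] | pd.DataFrame,
    min_count: int = 50,
) -> dict:
    """Recovered-vs-injected audit for synthetic runs.

    Reports the injected and recovered offset-0 misincorporation rates, a
    per-substitution confusion table, the total-variation distance between
    injected and recovered substitution spectra, and hotspot recall/precision
    against positions whose injected event count exceeds ``min_count``.
    """
    frame = truth if isinstance(truth, pd.DataFrame) else truth_table_frame(truth)
    per_read = frame.drop_duplicates("read_id")
    injected_percent = 100.0 * per_read["misinc_ec"].mean() if len(per_read) else 0.0

    mis = frame[frame["layer"] == "misincorporation"]
    injected_subs = (mis["tmpl"] + ">" + mis["obs"]).value_counts().to_dict()

    recovered_subs: dict[str, int] = {}
    recovered_percent = report.misincorporated_ec_percent
    if report.error_table is not None:
        recovered_subs = {
            sub: int(c)
            for sub, c in report.error_table.specific_counts.iloc[0].items()
            if c > 0
        }

    labels = sorted(set(injected_subs) | set(recovered_subs))
    confusion = {
        lab: {
            "injected": int(injected_subs.get(lab, 0)),
            "recovered": int(recovered_subs.get(lab, 0)),
        }
        for lab in labels
    }
    tot_i = sum(injected_subs.values())
    tot_r = sum(recovered_subs.values())
    if tot_i and tot_r:
        tv = 0.5 * sum(
            abs(injected_subs.get(l, 0) / tot_i - recovered_subs.get(l, 0) / tot_r)
            for l in labels
        )
    else:
        tv = None

    true_hot = (
        mis.groupby(["contig", "strand", "pos3"]).size() if len(mis) else pd.Series(dtype=int)
    )
    true_positions = {
        (c, s, int(p)) for (c, s, p), n in true_hot.items() if n > min_count
    }
    called_positions = {(h.contig, h.strand, h.position) for h in report.hotspots}
    overlap = true_positions & called_positions
    recall = len(overlap) / len(true_positions) if true_positions else None
    precision = len(overlap) / len(called_positions) if called_positions else None

    return {
        "injected_misinc_percent": float(injected_percent),
        "recovered_misinc_percent": recovered_percent,
        "substitution_confusion": confusion,
        "spectrum_total_variation_distance": tv,
        "hotspot_recall": recall,
        "hotspot_precision": precision,
        "n_true_hotspots": len(true_positions),
        "n_called_hotspots": len(called_positions),
    }
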