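"""Region classification and per-100 kb misincorporation densities.

Misincorporation locations are classified as translated (inside a CDS on the
matching strand), transcribed-untranslated (inside a UTR, plus introns in
yeast mode, on the matching strand) or other. Densities are reported per
100 000 bases of merged class footprint; footprints are counted per strand
and summed, since locations are strand-resolved.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import gffutils
import numpy as np
import pandas as pd

from .context import Hotspot
from .genome import AnnotationSet, Interval, ReferenceGenome, merge_intervals, merged_length, read_bed

CLASSES = ("translated", "transcribed_untranslated", "other")


def load_annotation(
    gff3_path: str | Path,
    utr_bed_path: str | Path | None = None,
    mode: str = "bacteria",
) -> AnnotationSet:
    """CDS from GFF3 (1-based inclusive -> half-open), UTR/introns from BED.

    BED rows named ``intron`` feed the intron list, used only in yeast mode;
    every other row is a UTR. Same-strand CDS/UTR overlap is rejected.
    """
    if mode not in ("bacteria", "yeast"):
        raise ValueError(f"mode must be 'bacteria' or 'yeast', got {mode!r}")
    db = gffutils.create_db(
        str(gff3_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    annotation = AnnotationSet()
    for feat in db.features_of_type("CDS"):
        annotation.cds.append(
            Interval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        )
    if utr_bed_path is not None:
        for iv, name in read_bed(utr_bed_path):
            if name.lower().startswith("intron"):
                if mode == "yeast":
                    annotation.introns.append(iv)
            else:
                annotation.utr.append(iv)
    annotation.validate()
    return annotation


class _StrandLookup:
    """Merged sorted intervals per (contig, strand) with binary-search queries."""

    def __init__(self, intervals: Sequence[Interval]):
        self._tables: dict[tuple[str, str], tuple[np.ndarray, np.ndarray]] = {}
        grouped: dict[tuple[str, str], list[tuple[int, int]]] = {}
        for iv in intervals:
            grouped.setdefault((iv.contig, iv.strand), []).append((iv.start, iv.end))
        for key, pairs in grouped.items():
            merged = merge_intervals(pairs)
            starts = np.array([s for s, _ in merged], dtype=np.int64)
            ends = np.array([e for _, e in merged], dtype=np.int64)
            self._tables[key] = (starts, ends)

    def contains(self, contig: str, positions: np.ndarray, strand: str) -> np.ndarray:
        table = self._tables.get((contig, strand))
        if table is None:
            return np.zeros(len(positions), dtype=bool)
        starts, ends = table
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = idx >= 0
        hit = np.zeros(len(positions), dtype=bool)
        hit[ok] = positions[ok] < ends[idx[ok]]
        return hit


@dataclass
class RegionClassifier:
    annotation: AnnotationSet
    mode: str = "bacteria"

    def __post_init__(self) -> None:
        untranslated = list(self.annotation.utr)
        if self.mode == "yeast":
            untranslated += list(self.annotation.introns)
        self._cds = _StrandLookup(self.annotation.cds)
        self._untranslated = _StrandLookup(untranslated)
        self._untranslated_intervals = untranslated

    def classify(self, contig: str, position: int, strand: str) -> str:
        return self.classify_many(contig, np.array([position]), strand)[0]

    def classify_many(
        self, contig: str, positions: np.ndarray, strand: str
    ) -> np.ndarray:
        out = np.full(len(positions), "other", dtype=object)
        in_utr = self._untranslated.contains(contig, positions, strand)
        out[in_utr] = "transcribed_untranslated"
        in_cds = self._cds.contains(contig, positions, strand)
        out[in_cds] = "translated"  # translated takes precedence
        return out

    def class_lengths(self, genome: ReferenceGenome) -> dict[str, int]:
        translated = merged_length(self.annotation.cds)
        untranslated = merged_length(self._untranslated_intervals)
        total = 2 * genome.total_length  # both strands
        return {
            "translated": translated,
            "transcribed_untranslated": untranslated,
            "other": total - translated - untranslated,
        }


def classify_position(
    contig: str, position: int, strand: str, annotation: AnnotationSet, mode: str = "bacteria"
) -> str:
    """Class of one strand-resolved genomic location."""
    return RegionClassifier(annotation, mode).classify(contig, position, strand)


def region_rate_table(
    events: pd.DataFrame,
    hotspots: Sequence[Hotspot],
    annotation: AnnotationSet,
    genome: ReferenceGenome,
    mode: str = "bacteria",
) -> pd.DataFrame:
    """Per-class location/EC counts and densities per 100 kb.

    ``n_locations`` counts distinct (contig, position, strand) tuples of
    offset-0 events; ``n_ecs`` counts the events themselves. Hotspot counts
    and densities use the supplied hotspot list. Zero-length classes get NaN
    densities.
    """
    classifier = RegionClassifier(annotation, mode)
    lengths = classifier.class_lengths(genome)

    at3 = events[events["offset"] == 0]
    rows = {c: {"n_locations": 0, "n_ecs": 0, "hotspots": 0} for c in CLASSES}
    if len(at3):
        grouped = at3.groupby(["contig", "strand"])
        for (contig, strand), sub in grouped:
            counts = sub.groupby("position").size()
            positions = counts.index.to_numpy(dtype=np.int64)
            classes = classifier.classify_many(contig, positions, strand)
            for cls in CLASSES:
                sel = classes == cls
                rows[cls]["n_locations"] += int(sel.sum())
                rows[cls]["n_ecs"] += int(counts.to_numpy()[sel].sum())
    for h in hotspots:
        cls = classifier.classify(h.contig, h.position, h.strand)
        rows[cls]["hotspots"] += 1

    records = []
    for cls in CLASSES:
        length = lengths[cls]
        loc = rows[cls]["n_locations"]
        hs = rows[cls]["hotspots"]
        records.append(
            {
                "region_class": cls,
                "n_locations": loc,
                "n_ecs": rows[cls]["n_ecs"],
                "length_bp": length,
                "locations_per_100kb": 100_000 * loc / length if length else np.nan,
                "hotspots": hs,
                "hotspots_per_100kb": 100_000 * hs / length if length else np.nan,
            }
        )
    return pd.DataFrame(records).set_index("region_class")
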