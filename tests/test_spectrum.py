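"""Per-position error rates: extraction rules, table arithmetic, sweeps."""

import numpy as np
import pandas as pd
import pytest

import oracles
from netseq_fidelity.align import Alignment, GenomeIndex, align_reads
from netseq_fidelity.genome import ReferenceGenome
from netseq_fidelity.preprocess import ReadRecord
from netseq_fidelity.simulate import SimConfig, simulate
from netseq_fidelity.spectrum import (
    extract_mismatch_events,
    misincorporated_ec_fraction,
    positional_error_table,
    read_events,
    threshold_sweep,
    write_events,
)
from netseq_fidelity.varmask import Variant, VariantSet


@pytest.fixture(scope="module")
def toy():
    genome = ReferenceGenome({"c1": "ACGTACGTACGTACGTGACT"})
    return genome


def one_read(genome, start=0, length=16, mutate_at=None, new_base="A", qual=38):
    seq = list(genome.contigs["c1"][start : start + length])
    quals = np.full(length, 38)
    offsets = []
    if mutate_at is not None:
        seq[mutate_at] = new_base
        quals[mutate_at] = qual
        offsets = [mutate_at - (length - 1)]
    read = ReadRecord("r1", "".join(seq), quals)
    aln = Alignment("r1", "c1", start, "+", length, np.array(offsets, dtype=int))
    return read, aln


class TestExtraction:
    def test_high_quality_terminal_mismatch_is_event(self, toy):
        # template G at the 3' terminus replaced by A, Q=35 -> one G>A event
        read, aln = one_read(toy, start=0, length=15, mutate_at=14, new_base="A", qual=35)
        assert toy.contigs["c1"][14] == "G"
        events, denom = extract_mismatch_events([aln], {"r1": read}, toy)
        assert len(events) == 1
        ev = events.iloc[0]
        assert (ev["offset"], ev["substitution"], ev["position"]) == (0, "G>A", 14)
        assert denom[0] == 1

    def test_low_quality_mismatch_excluded_but_denominator_counts(self, toy):
        read, aln = one_read(toy, start=0, length=15, mutate_at=14, new_base="A", qual=29)
        events, denom = extract_mismatch_events([aln], {"r1": read}, toy)
        assert len(events) == 0
        assert denom[0] == 1

    def test_event_at_variant_position_excluded(self, toy):
        read, aln = one_read(toy, start=0, length=15, mutate_at=14, new_base="A", qual=38)
        variants = VariantSet([Variant("c1", 14, "G", "A", 1.0, 50)])
        events, _ = extract_mismatch_events([aln], {"r1": read}, toy, variants=variants)
        assert len(events) == 0

    def test_n_read_base_excluded_from_denominator_and_events(self, toy):
        seq = list(toy.contigs["c1"][:15])
        seq[14] = "N"
        read = ReadRecord("r1", "".join(seq), np.full(15, 38))
        aln = Alignment("r1", "c1", 0, "+", 15, np.array([0], dtype=int))
        events, denom = extract_mismatch_events([aln], {"r1": read}, toy)
        assert len(events) == 0
        assert denom[0] == 0 and denom[1] == 1

    def test_minus_strand_template_reported_in_transcript_space(self, toy):
        # read is revcomp of forward slice; mutate its 3' terminal base
        from netseq_fidelity.genome import revcomp

        start, length = 2, 16
        seq = list(revcomp(toy.contigs["c1"][start : start + length]))
        tmpl = seq[-1]
        new = "A" if tmpl != "A" else "G"
        seq[-1] = new
        read = ReadRecord("r1", "".join(seq), np.full(length, 38))
        aln = Alignment("r1", "c1", start, "-", length, np.array([0], dtype=int))
        events, _ = extract_mismatch_events([aln], {"r1": read}, toy)
        ev = events.iloc[0]
        assert ev["substitution"] == f"{tmpl}>{new}"
        assert ev["position"] == start  # 3' terminus maps to the leftmost base
        assert ev["strand"] == "-"

    def test_negative_phred_min_rejected(self, toy):
        read, aln = one_read(toy)
        with pytest.raises(ValueError):
            extract_mismatch_events([aln], {"r1": read}, toy, phred_min=-1)


class TestTableArithmetic:
    def test_rate_is_percentage_of_denominator(self):
        events = pd.DataFrame(
            {
                "read_id": [f"r{i}" for i in range(30)],
                "contig": ["c1"] * 30,
                "position": list(range(30)),
                "strand": ["+"] * 30,
                "offset": [0] * 30,
                "template_base": ["G"] * 30,
                "read_base": ["A"] * 30,
                "quality": [38] * 30,
                "substitution": ["G>A"] * 30,
            }
        )
        denom = np.array([1000, 1000])
        table = positional_error_table(events, denom)
        assert table.total_rate(0) == 3.0
        assert misincorporated_ec_fraction(table) == 3.0
        assert table.specific_counts.loc[0, "G>A"] == 30

    def test_no_events_all_zero_rates(self):
        denom = np.array([100, 100, 100])
        table = positional_error_table(pd.DataFrame(), denom)
        assert (table.total_rate_percent == 0).all()

    def test_zero_denominator_reported_missing(self):
        table = positional_error_table(pd.DataFrame(), np.array([100, 0]))
        assert np.isnan(table.total_rate(-1))
        with pytest.raises(ValueError):
            misincorporated_ec_fraction(
                positional_error_table(pd.DataFrame(), np.array([0]))
            )

    def test_specific_counts_sum_to_mismatch_count(self, small_bundle):
        index = GenomeIndex(small_bundle.reference)
        alignments, _ = align_reads(small_bundle.reads, index)
        by_id = {r.read_id: r for r in small_bundle.reads}
        events, denom = extract_mismatch_events(alignments, by_id, small_bundle.reference)
        table = positional_error_table(events, denom)
        assert (
            table.specific_counts.sum(axis=1).to_numpy() == table.mismatch_reads
        ).all()


class TestOracleRecount:
    def test_table_equals_naive_double_loop(self, small_bundle):
        reads = small_bundle.reads[:4_000]
        index = GenomeIndex(small_bundle.reference)
        alignments, _ = align_reads(reads, index)
        by_id = {r.read_id: r for r in reads}
        events, denom = extract_mismatch_events(alignments, by_id, small_bundle.reference)
        table = positional_error_table(events, denom)
        n_denom, n_mm, n_spec = oracles.naive_error_table(
            alignments, by_id, small_bundle.reference.contigs
        )
        assert list(table.denominators) == n_denom
        assert list(table.mismatch_reads) == n_mm
        for k in range(table.window):
            for sub, count in n_spec[k].items():
                assert table.specific_counts.loc[k, sub] == count


class TestRecovery:
    def test_zero_noise_interior_offsets_silent_and_terminal_recovers(self):
        cfg = SimConfig(
            genome_length=30_000,
            n_genes=8,
            n_ecs=20_000,
            misinc_fraction=0.04,
            rt_error_rate=0.0,
            pcr_error_rate=0.0,
            seq_error_rate=0.0,
            readthrough_rate=0.0,
            seed=71,
        )
        bundle = simulate(cfg)
        index = GenomeIndex(bundle.reference)
        alignments, _ = align_reads(bundle.reads, index)
        by_id = {r.read_id: r for r in bundle.reads}
        events, denom = extract_mismatch_events(alignments, by_id, bundle.reference)
        table = positional_error_table(events, denom)
        assert np.allclose(table.total_rate_percent[1:], 0.0)
        n = denom[0]
        half = 2.576 * np.sqrt(0.04 * 0.96 / n)
        assert abs(table.total_rate(0) / 100 - 0.04) <= half
        # the G>A-dominant default spectrum shows up as the modal substitution
        assert table.specific_counts.loc[0].idxmax() == "G>A"

    def test_readthrough_produces_u_to_c_at_minus_one_and_two(self):
        cfg = SimConfig(
            genome_length=30_000,
            n_genes=8,
            n_ecs=20_000,
            misinc_fraction=0.0,
            rt_error_rate=0.0,
            pcr_error_rate=0.0,
            seq_error_rate=0.0,
            readthrough_rate=0.02,
            seed=72,
        )
        bundle = simulate(cfg)
        index = GenomeIndex(bundle.reference)
        alignments, _ = align_reads(bundle.reads, index)
        by_id = {r.read_id: r for r in bundle.reads}
        events, denom = extract_mismatch_events(alignments, by_id, bundle.reference)
        table = positional_error_table(events, denom)
        for k in (1, 2):
            assert table.specific_counts.loc[k].idxmax() == "T>C"
            assert table.total_rate_percent[k] > 0
        assert np.allclose(table.total_rate_percent[3:], 0.0)


class TestThresholdSweep:
    def _events_with_counts(self, counts):
        rows = []
        rid = 0
        for pos, c in enumerate(counts):
            for _ in range(c):
                rows.append((f"r{rid}", "c1", pos, "+", 0, "G", "A", 38, "G>A"))
                rid += 1
        return pd.DataFrame(
            rows,
            columns=[
                "read_id", "contig", "position", "strand", "offset",
                "template_base", "read_base", "quality", "substitution",
            ],
        )

    def test_hand_enumerated_counts(self):
        events = self._events_with_counts([1, 1, 60])
        sweep = threshold_sweep(events, thresholds=[0, 50])
        at0 = sweep[sweep["threshold"] == 0].iloc[0]
        assert (at0["n_positions"], at0["n_ecs"]) == (3, 62)
        at50 = sweep[sweep["threshold"] == 50].iloc[0]
        assert (at50["n_positions"], at50["n_ecs"]) == (1, 60)

    def test_threshold_beyond_max_gives_zero(self):
        events = self._events_with_counts([2, 3])
        sweep = threshold_sweep(events, thresholds=[10])
        assert (sweep.iloc[0][["n_positions", "n_ecs"]] == 0).all()

    def test_series_non_increasing(self, small_bundle):
        index = GenomeIndex(small_bundle.reference)
        alignments, _ = align_reads(small_bundle.reads, index)
        by_id = {r.read_id: r for r in small_bundle.reads}
        events, _ = extract_mismatch_events(alignments, by_id, small_bundle.reference)
        sweep = threshold_sweep(events)
        assert (np.diff(sweep["n_positions"]) <= 0).all()
        assert (np.diff(sweep["n_ecs"]) <= 0).all()
        assert sweep.iloc[0]["n_ecs"] == (events["offset"] == 0).sum()


class TestEventsIO:
    def test_events_tsv_round_trip(self, tmp_path, small_bundle):
        index = GenomeIndex(small_bundle.reference)
        alignments, _ = align_reads(small_bundle.reads[:2_000], index)
        by_id = {r.read_id: r for r in small_bundle.reads[:2_000]}
        events, _ = extract_mismatch_events(alignments, by_id, small_bundle.reference)
        path = tmp_path / "events.tsv"
        write_events(events, path)
        back = read_events(path)
        for col in ("contig", "position", "strand", "offset", "substitution", "read_id"):
            assert list(back[col]) == list(events[col])
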