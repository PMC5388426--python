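"""Synthetic data generator: determinism, placement, and injected-error rates."""

import numpy as np
import pytest
from scipy import stats

from netseq_fidelity.genome import revcomp
from netseq_fidelity.simulate import (
    DEFAULT_SPECTRUM,
    SimConfig,
    generate_genome,
    plant_variants,
    sample_elongation_complexes,
    simulate,
    synthesize_reads,
    truth_table_frame,
)


class TestGenerateGenome:
    def test_no_genes_yields_empty_annotation(self):
        cfg = SimConfig(genome_length=5_000, n_genes=0, seed=1)
        genome, annotation = generate_genome(cfg)
        assert genome.total_length == 5_000
        assert annotation.genes == [] and annotation.cds == [] and annotation.utr == []

    def test_deterministic_given_seed(self):
        cfg = SimConfig(genome_length=30_000, n_genes=5, seed=7)
        g1, a1 = generate_genome(cfg)
        g2, a2 = generate_genome(cfg)
        assert g1.contigs == g2.contigs
        assert a1.cds == a2.cds and a1.utr == a2.utr

    def test_gc_fraction_within_three_sd_of_binomial(self):
        n = 100_000
        cfg = SimConfig(genome_length=n, gc_fraction=0.5, n_genes=0, seed=11)
        genome, _ = generate_genome(cfg)
        seq = genome.contigs["contig_1"]
        gc = (seq.count("G") + seq.count("C")) / n
        sd = np.sqrt(0.5 * 0.5 / n)
        assert abs(gc - 0.5) <= 3 * sd

    def test_genes_do_not_overlap_and_cds_multiple_of_three(self):
        cfg = SimConfig(genome_length=60_000, n_genes=12, seed=5)
        _, annotation = generate_genome(cfg)
        spans = sorted((g.tx_start, g.tx_end) for g in annotation.genes)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            assert e1 <= s2
        for iv in annotation.cds:
            assert (iv.end - iv.start) % 3 == 0

    def test_fails_when_genes_cannot_fit(self):
        cfg = SimConfig(genome_length=2_000, n_genes=10, seed=1)
        with pytest.raises(ValueError, match="without overlap"):
            generate_genome(cfg)


class TestSampleElongationComplexes:
    def test_positions_inside_single_gene_span(self):
        cfg = SimConfig(genome_length=5_000, n_genes=1, n_ecs=5, seed=2)
        genome, annotation = generate_genome(cfg)
        gene = annotation.genes[0]
        ecs = sample_elongation_complexes(genome, annotation, cfg)
        assert len(ecs) == 5
        for ec in ecs:
            assert gene.tx_start <= ec.position < gene.tx_end
            assert ec.strand == gene.strand
            # a full-length read upstream of the 3' end stays in the transcript
            if ec.strand == "+":
                assert ec.position - (cfg.read_length_max - 1) >= gene.tx_start
            else:
                assert ec.position + cfg.read_length_max <= gene.tx_end

    def test_zero_weight_gene_receives_no_ecs(self):
        cfg = SimConfig(genome_length=20_000, n_genes=4, n_ecs=500, seed=3)
        genome, annotation = generate_genome(cfg)
        weights = [1.0, 0.0, 1.0, 1.0]
        ecs = sample_elongation_complexes(genome, annotation, cfg, weights=weights)
        dead = annotation.genes[1]
        assert all(not (dead.tx_start <= ec.position < dead.tx_end) for ec in ecs)

    def test_uniform_weights_follow_multinomial(self):
        cfg = SimConfig(genome_length=60_000, n_genes=6, n_ecs=12_000, seed=4)
        genome, annotation = generate_genome(cfg)
        ecs = sample_elongation_complexes(
            genome, annotation, cfg, weights=[1.0] * 6
        )
        counts = np.zeros(6)
        for ec in ecs:
            for gi, g in enumerate(annotation.genes):
                if g.tx_start <= ec.position < g.tx_end:
                    counts[gi] += 1
                    break
        res = stats.chisquare(counts)
        assert res.pvalue > 0.001

    def test_fails_without_long_enough_transcript(self):
        cfg = SimConfig(genome_length=20_000, n_genes=4, n_ecs=10, seed=3)
        genome, annotation = generate_genome(cfg)
        with pytest.raises(ValueError, match="no transcript long enough|weight"):
            sample_elongation_complexes(genome, annotation, cfg, weights=[0, 0, 0, 0])


class TestSynthesizeReads:
    def test_error_free_reads_are_exact_transcript_substrings(self, clean_bundle):
        genome = clean_bundle.reference.contigs["contig_1"]
        for read, rec in zip(clean_bundle.reads, clean_bundle.truth):
            L = len(read.sequence)
            p = rec.genomic_3prime_position
            if rec.strand == "+":
                assert read.sequence == genome[p - L + 1 : p + 1]
            else:
                assert read.sequence == revcomp(genome[p : p + L])
            assert rec.injected_events == []

    def test_full_misincorporation_with_pure_g_to_a_spectrum(self):
        cfg = SimConfig(
            genome_length=20_000,
            n_genes=6,
            n_ecs=2_000,
            misinc_fraction=1.0,
            substitution_spectrum={"G>A": 1.0},
            rt_error_rate=0.0,
            pcr_error_rate=0.0,
            seq_error_rate=0.0,
            seed=21,
        )
        bundle = simulate(cfg)
        assert all(t.is_misincorporated_ec for t in bundle.truth)
        genome = bundle.reference.contigs["contig_1"]
        for read, rec in zip(bundle.reads, bundle.truth):
            p = rec.genomic_3prime_position
            tmpl = genome[p] if rec.strand == "+" else revcomp(genome[p])
            if tmpl == "G":
                assert read.sequence[-1] == "A"
                assert rec.injected_events[0].layer == "misincorporation"
            else:
                assert read.sequence[-1] == tmpl  # no event possible

    def test_sequencing_layer_event_count_within_poisson_bound(self):
        n_reads, length, rate = 20_000, 25, 1e-3
        cfg = SimConfig(
            genome_length=30_000,
            n_genes=6,
            n_ecs=n_reads,
            misinc_fraction=0.0,
            rt_error_rate=0.0,
            pcr_error_rate=0.0,
            seq_error_rate=rate,
            read_length_min=length,
            read_length_max=length,
            seed=31,
        )
        bundle = simulate(cfg)
        n_seq = sum(
            1 for t in bundle.truth for ev in t.injected_events if ev.layer == "sequencing"
        )
        expected = rate * length * n_reads
        assert abs(n_seq - expected) <= 3 * np.sqrt(expected)

    def test_truth_conservation_and_event_consistency(self, small_bundle):
        assert len(small_bundle.truth) == len(small_bundle.reads)
        for read, rec in zip(small_bundle.reads, small_bundle.truth):
            assert read.read_id == rec.read_id
            L = len(read.sequence)
            final: dict[int, str] = {}
            for ev in rec.injected_events:
                assert ev.offset <= 0
                final[ev.offset] = ev.read_base
            for off, base in final.items():
                assert read.sequence[L - 1 + off] == base

    def test_misincorporated_fraction_within_99_ci(self, small_bundle, small_config):
        n = len(small_bundle.truth)
        p = small_config.misinc_fraction
        observed = sum(t.is_misincorporated_ec for t in small_bundle.truth) / n
        half = 2.576 * np.sqrt(p * (1 - p) / n)
        assert abs(observed - p) <= half

    def test_misincorporation_positions_uniform_without_boost(self):
        cfg = SimConfig(
            genome_length=4_000,
            n_genes=1,
            n_ecs=30_000,
            misinc_fraction=0.5,
            hotspot_motif_boost=1.0,
            rt_error_rate=0.0,
            pcr_error_rate=0.0,
            seq_error_rate=0.0,
            seed=41,
        )
        bundle = simulate(cfg)
        positions = [
            t.genomic_3prime_position for t in bundle.truth if t.is_misincorporated_ec
        ]
        gene = bundle.annotation.genes[0]
        lo = gene.tx_start + cfg.read_length_max - 1 if gene.strand == "+" else gene.tx_start
        hi = lo + gene.tx_length - cfg.read_length_max + 1
        hist, _ = np.histogram(positions, bins=10, range=(lo, hi))
        res = stats.chisquare(hist)
        assert res.pvalue > 0.001

    def test_empty_ec_list_rejected(self, clean_bundle, clean_config):
        with pytest.raises(ValueError, match="empty"):
            synthesize_reads([], clean_bundle.reference, clean_config)


class TestPlantVariants:
    def test_variants_written_into_every_overlapping_read(self):
        cfg = SimConfig(
            genome_length=20_000,
            n_genes=6,
            n_ecs=4_000,
            misinc_fraction=0.0,
            rt_error_rate=0.0,
            pcr_error_rate=0.0,
            seq_error_rate=0.0,
            variant_positions=8,
            seed=51,
        )
        bundle = simulate(cfg)
        assert len(bundle.variants) == 8
        variant_map = {v.position: v for v in bundle.variants}
        ref = bundle.reference.contigs["contig_1"]
        checked = 0
        for read, rec in zip(bundle.reads, bundle.truth):
            L = len(read.sequence)
            for k in range(L):
                if rec.strand == "+":
                    pos = rec.genomic_3prime_position - (L - 1) + k
                    base = read.sequence[k]
                else:
                    pos = rec.genomic_3prime_position + (L - 1) - k
                    base = read.sequence[k].translate(str.maketrans("ACGT", "TGCA"))
                if pos in variant_map:
                    assert base == variant_map[pos].alt
                    assert ref[pos] == variant_map[pos].ref
                    checked += 1
        assert checked > 0


class TestDeterminism:
    def test_same_seed_bytewise_identical_reads_and_truth(self, small_config):
        b1, b2 = simulate(small_config), simulate(small_config)
        assert [r.sequence for r in b1.reads] == [r.sequence for r in b2.reads]
        assert all(
            (q1 == q2).all() for q1, q2 in zip(
                (r.qualities for r in b1.reads), (r.qualities for r in b2.reads)
            )
        )
        assert truth_table_frame(b1.truth).equals(truth_table_frame(b2.truth))

    def test_config_invariants_enforced(self):
        with pytest.raises(ValueError, match="spectrum"):
            SimConfig(substitution_spectrum={"G>A": 0.5}).validate()
        with pytest.raises(ValueError, match="seed length"):
            SimConfig(read_length_min=10).validate()
        total = sum(DEFAULT_SPECTRUM.values())
        assert abs(total - 1.0) < 1e-9
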