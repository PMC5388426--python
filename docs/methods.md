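# Methods

## What is being measured

In NET-seq, the sequenced fragment ends at the 3′ terminus of a nascent RNA
still engaged with RNA polymerase. A mismatch at the terminal aligned base
therefore marks an elongation complex (EC) that has just added a
non-templated nucleotide. Because misincorporation stabilises backtracking,
such complexes persist and accumulate; the fraction of reads with a
quality-passing terminal mismatch estimates the standing proportion of
misincorporated ECs. Reads are handled throughout in **transcript space**:
the read string runs 5′→3′ along the RNA (minus-strand reads are the reverse
complement of the forward genome slice), so the last character of the string
is the nascent 3′ terminus and "offset from the 3′ end" equals offset from
the end of the string. RNA bases are stored in the DNA alphabet (U as T);
substitution labels are template>read ("G>A" = AMP added where GMP was
templated).

## Pipeline stages and their parameters

**Preprocessing.** Optional exact suffix–prefix adapter trimming (minimum
overlap 3), a minimum-length filter (default 16 nt, never below the aligner
seed length), and exclusion of reads whose base at the position adjacent to
the 3′ terminus (read offset −1) is N — that read position is prone to a
systematic sequencing artefact. Contaminant loci (tRNA/rRNA/snoRNA
stand-ins) are handled as a post-alignment blacklist-interval rejection
rather than a separate contaminant alignment pass: at this scale one index
with interval rejection is equivalent and simpler.

**Alignment.** Ungapped, seed-anchored, unique-only. The seed is the 14
bases at the read's 3′ end — the end that carries the misincorporation; in
this library protocol the sequenced 5′ end corresponds to the nascent 3′
terminus, so a transcript-space 3′ seed coincides with a sequenced-read 5′
seed while stating the policy independently of sequencing chemistry. A
candidate placement must match the seed with ≤2 substitutions (a pure count,
not a quality-weighted sum); extension over the rest of the read is
unlimited in mismatches, because full-length mismatches are the signal being
measured. Candidates are ranked by total mismatch count and any tie in the
best stratum rejects the read as multimapped — the conservative reading of
"report unique alignments only", applied even when one tied candidate has
fewer seed mismatches. Candidate generation splits the seed into three parts
(5+5+4); by pigeonhole every placement with ≤2 seed mismatches matches one
part exactly, so exact-match part indexes over both strands find all
candidates, with a fast path through a full-seed exact index for placements
with zero total mismatches (any tie against a zero-mismatch placement must
itself be a zero-mismatch, exact-seed placement, so the uniqueness decision
needs no wider search). On small genomes the aligner is verified against an
exhaustive scorer that evaluates every placement on both strands. Circular
contigs are supported by letting seeds and extensions wrap (bacterial
chromosomes); the synthetic genome is linear by default. A k-mer uniqueness
report (every instance over both strands, N-containing k-mers excluded)
documents that 14-mers are effectively unique on the genomes analysed, which
is what justifies the seed length.

**Variant masking.** A laboratory strain differs from its reference at a
handful of positions that would otherwise be read as mismatches at every
coverage depth. Variants are called from a strand-pooled pileup with a
depth/fraction threshold caller: depth ≥10 non-N bases and a single
most-frequent non-reference base at ≥0.8 of depth. Homozygous strain
variants sit near fraction 1.0 while misincorporation signal stays far below
0.8 at any realistic per-position EC density, so a likelihood model adds
nothing here; both thresholds are configurable. Variants are called per
genomic position pooled across strands, since a genomic mutation affects
both. All events at called positions are excluded from every downstream
statistic.

**Spectrum.** For each aligned read and offset 0…−(W−1), the denominator
counts the read when its base there is not N; a mismatch event requires
read ≠ reference (transcript space), neither base N, Phred ≥30 (99.9%
base-call accuracy), and no variant at the position. The default window W=11
(offsets 0…−10) approximately covers the RNA/DNA hybrid within the EC. Two
deliberate conventions, each exposed as a switch or documented: (i)
denominators count reads regardless of base quality — only the mismatch
classification is quality-thresholded (a `quality_in_denominator` switch
implements the alternative); (ii) a read mismatched at several offsets
counts once at each mismatched offset. The misincorporated-EC proportion is
the total rate at offset 0. The threshold sweep groups offset-0 events by
(contig, position, strand), pooling substitution types, and reports how many
positions and how many events survive as the per-position count threshold
rises; both series are non-increasing by construction.

**Hotspots and context.** A hotspot is a position with strictly more than 50
offset-0 events. The threshold applies per substitution class by default
(hotspots are typically discussed per class, e.g. G>A), with a pooled
`"all"` mode, because both conventions are useful. Context windows (default
halfwidth 5; the window size is a free choice and configurable) are reported
in transcript orientation with the misincorporated position at index 0:
negative offsets are already-transcribed RNA bases, positive offsets are
not-yet-transcribed template positions read from the non-template strand.
The position frequency matrix is per-position and unweighted by event count;
N entries drop out of their column's denominator, and all-N columns are
flagged missing. A simple matplotlib frequency logo can be rendered from the
PFM.

**Regions.** Positions are classified translated (inside a CDS on the
matching strand), transcribed-untranslated (UTR, plus introns in yeast
mode, matching strand) or other, with translated taking precedence on
same-strand overlap and strand match deciding before anything else.
Densities are per 100 000 bp of merged class footprint. Footprints are
counted per strand and summed — locations are strand-resolved, so a position
under features on both strands contributes twice. Whether published
region tables used single-strand or strand-summed lengths is ambiguous;
this affects absolute densities only, not the translated/untranslated
contrast, and the convention used here is stated so the tables are well
defined. UTR discovery tools are out of scope; UTR/intron intervals are an
input (BED).

**Accuracy model.** The experimental layers compose additively,
p_exp = p_RT + n_cycles·p_PCR + p_seq; with all rates ≤10⁻³ the neglected
second-order terms are ≤10⁻⁶, below reporting precision, and a Monte-Carlo
simulation of the three layers in the test suite quantifies the
approximation. A genuine mismatch survives a superimposed error with
probability 2/3 (the error lands uniformly on the three non-template bases,
one of which is the template); this retention factor is exposed for
sensitivity analysis. Defaults: p_RT = 1×10⁻⁴ per base (reverse
transcriptases do not proofread; published rates are 10⁻⁴–10⁻⁵),
p_seq = 1×10⁻³ (the residual miscall rate behind a Phred-30 filter),
p_PCR = 4×10⁻⁷ per base per cycle over 15 cycles — the PCR values are
declared defaults for a high-fidelity polymerase, labelled as such in
output, since vendor datasheets rather than printed numbers are the source.
Observed rates at or below p_exp invert to a true rate of 0 (with a
warning). The model is exactly invertible: the round trip
r → observed → r is identity to 10⁻¹².

## The synthetic data generator

The generator emulates the statistical structure the analysis assumes, with
full ground truth. Defaults define the study conditions: a 200 kb random
genome at GC 0.5 with 40 non-overlapping genes (5′UTR 50 nt, CDS 300–1500 nt
divisible by 3, 3′UTR 100 nt) on both strands; 2×10⁵ ECs placed inside
transcribed spans, at least a full read length downstream of the transcript
start, with lognormal (σ=1) per-gene abundances; reads of 16–30 nt; planted
homozygous strain variants written into every overlapping read (an
unambiguous recovery target for the variant caller); RT/PCR/sequencing
layers at the accuracy-model defaults, the PCR layer folded into one
per-base Bernoulli at cycles × per-cycle rate (no lineage simulation — the
additive small-rate model is the quantity of interest); and Phred scores
from a two-component model, correct bases ~N(38,2) and sequencing miscalls
~N(22,6), both truncated to [2,40] and rounded, so that the Q30 filter is
genuinely exercised: it removes ~90% of sequencing miscalls while retaining
essentially all pre-sequencing (biological, RT, PCR) mismatches, which carry
correct-base qualities because the molecule itself was changed.

An EC's misincorporation flag is Bernoulli(misinc_fraction), independent of
its template base (boosted multiplicatively at C₋₁G₀ motifs when
hotspot_motif_boost > 1); the substitution is then drawn from the
12-class spectrum restricted to the template's row and renormalised. The
realised class mix is therefore the row-conditional spectrum weighted by
template-base availability at EC 3′ ends, not the raw 12-class vector; the
default spectrum's weights were chosen so that G>A remains clearly modal
after this reweighting on a 50% GC genome. U>C read-through errors are
injected independently at offsets −1 and −2 (template T → read C) at
readthrough_rate, default 0 — the phenomenon is specific to the eukaryotic
datasets and is exercised by tests with the rate turned on. The read-length
distribution of real libraries is not fixed by the protocol, so it is left
configurable (uniform 16–30 by default).

What the generator does **not** emulate — and hence what passing tests do
not show about real data: base-composition- or sequence-dependent
experimental error rates; PCR jackpot lineages and duplicate reads;
position-within-read quality decay; pausing-driven non-uniform EC density
beyond per-gene abundance; indels (the analysis is substitutions-only);
RNA secondary structure; and real contaminant transcripts (the blacklist is
an interval stand-in). Recovery results on synthetic data validate the
bookkeeping and the statistical machinery, not the biology.

## Numerical and reproducibility choices

All coordinates are 0-based half-open internally; GFF3/SAM/VCF are emitted
1-based, BED 0-based. One run seed feeds independent `SeedSequence`
substreams per stage (genome, variants, EC placement, read synthesis), so a
stage can be toggled off and resumed from persisted artifacts without
perturbing the others; identical config + seed reproduces byte-identical
TSV/JSON outputs. Zero denominators yield missing (NaN/None) rates, never
zero. Ties in alignment rank are resolved by rejection (unique-only mode) or
first-in-stable-order otherwise. Problem sizes in the test and acceptance
runs (2×10⁵ reads on 200 kb for recovery; 10⁶ bases for the Monte-Carlo
cross-check; 100 random ≤5 kb genomes for the aligner-vs-oracle audit) were
chosen as the smallest sizes at which the 99% binomial confidence intervals
and 3-standard-deviation bounds being asserted are meaningfully tight.

## Known limitations

The aligner is ungapped and single-end by design — indels shift the 3′
anchor and are out of scope. The variant caller assumes homozygous,
well-covered variants; heterozygous or low-coverage variation would leak
into the spectrum. The accuracy model treats error rates as
base-composition independent. Hotspot calling uses a fixed count threshold,
not a coverage-normalised test, mirroring the analysis it reproduces; at
very uneven coverage a high-coverage position can cross the threshold by
depth alone.
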