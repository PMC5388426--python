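# netseq-fidelity

Transcription-fidelity analysis of nascent-RNA 3′ ends from NET-seq data.

NET-seq (Native Elongating Transcript sequencing) reads end exactly at the 3′
terminus of the RNA still held by a transcribing RNA polymerase, so a mismatch
at the very last aligned base of a read is not a mistake in a finished
transcript — it is a snapshot of an elongation complex (EC) that has just
misincorporated a nucleotide and, because misincorporation triggers
backtracking, is likely stalled. This package measures that signal: for each
offset from the 3′ end (0, −1, …, −10, roughly the RNA/DNA hybrid length) it
computes the fraction of reads carrying a quality-passing mismatch and splits
it into the 12 template→read substitution classes. The offset-0 total rate is
the **proportion of misincorporated ECs** in the cell population.

Around that core computation the package provides, as library modules and a
CLI (`netseq-fidelity`):

- `simulate` — a synthetic NET-seq generator (random genome with genes on
  both strands, EC placement with per-gene abundances, 3′-anchored reads with
  a configurable misincorporation fraction, a G>A-biased substitution
  spectrum, optional C₋₁G₀ hotspot enrichment, U>C read-through at −1/−2,
  planted strain variants, and RT/PCR/sequencing error layers with a Phred
  quality model) that records every injected event in a ground-truth table;
- `preprocess` — adapter trimming, minimum-length and N-at-3′-adjacent
  filters, blacklist rejection of contaminant loci;
- `align` — a unique, ungapped, seed-anchored aligner (seed = the 14 bases at
  the 3′ end, ≤2 seed mismatches, ambiguous reads rejected) plus a k-mer
  uniqueness audit over both strands that justifies the seed length;
- `varmask` — pileup + threshold variant calling so strain-vs-reference
  substitutions never masquerade as misincorporation;
- `spectrum` — the per-position total/specific error-rate tables, the
  misincorporated-EC fraction, and per-position event-count threshold sweeps;
- `context` — hotspot calling (positions with >50 events) and transcript-space
  sequence-context position frequency matrices (the numeric core of a logo);
- `regions` — translated vs transcribed-untranslated classification (GFF3 CDS
  + BED UTR/introns) with densities per 100 000 bp;
- `accuracy` — an error-propagation model for the experimental layers that
  estimates what percentage of observed mismatches are genuine;
- `pipeline` — one-seed orchestration of all stages with a consolidated JSON
  report and a recovered-vs-injected truth audit for synthetic runs.

## The model in brief

Substitutions are labelled template>read in transcript space (U written as T):
"G>A" means an A was incorporated where the template dictated G. Mismatch
calls are thresholded at Phred ≥ 30 (99.9% base-call accuracy); denominators
count every aligned read with a non-N base at the offset. The experimental
error budget composes additively,

    p_exp = p_RT + n_cycles · p_PCR + p_seq ,

and an observed mismatch rate r_obs relates to the true misincorporation rate
r_true by

    r_obs = r_true · (1 − p_exp · (1 − f)) + (1 − r_true) · p_exp ,  f = 2/3,

where f is the chance a genuine mismatch stays mismatched after a superimposed
error. Inverting this gives the true-positive percentage of the observed
signal. See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

```python
from netseq_fidelity import PipelineConfig, SimConfig, run

config = PipelineConfig(sim=SimConfig(n_ecs=50_000, misinc_fraction=0.05, seed=11))
report = run(config)
print("misincorporated EC fraction: %.2f%%" % report.misincorporated_ec_percent)
row0 = report.error_table.specific_counts.loc[0]
print("modal 3' substitution:", row0.idxmax(), int(row0.max()), "events")
print("estimated true-positive fraction at the 3' end: %.1f%%"
      % report.accuracy[0]["tp_fraction_percent"])
print(report.error_table.to_frame().iloc[:4, :4].to_string(index=False))
```

prints

```
misincorporated EC fraction: 4.95%
modal 3' substitution: G>A 531 events
estimated true-positive fraction at the 3' end: 97.9%
 offset  denominator_reads  mismatch_reads  total_rate_percent
      0              49996            2476            4.952396
     -1              49996               8            0.016001
     -2              49996               8            0.016001
     -3              49996              15            0.030002
```

Reading this: 5% of ECs were generated with a 3′-terminal misincorporation
and 4.95% were recovered after preprocessing, unique alignment, variant
masking and quality thresholding; the recovered substitution spectrum is
dominated by G>A as configured; interior offsets are near the experimental
noise floor; and the propagation model attributes ~98% of the offset-0 signal
to genuine misincorporation rather than library or sequencing error.

The same run from a shell:

```sh
netseq-fidelity run-all --out runs/demo --seed 11
netseq-fidelity accuracy --r-obs 0.03
```

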