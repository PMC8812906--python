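# fusiontriage

Fusion-gene callers routinely report dozens to hundreds of candidate
chimeric transcripts per tumor sample, and most of them are passengers —
artifacts of transcription, library preparation, or incidental
rearrangement with no role in the disease. `fusiontriage` separates the
likely **driver** fusions from the **passengers** by asking whether the
genome itself records the event: a genuine fusion is created by a
structural rearrangement and typically perturbs local gene dosage, so
its partner loci should carry both a structural-variant (SV) breakend
and a copy-number (CNV) segment change in the same sample.

The package is aimed at cancer genomics analysts who already have three
per-sample tables — SV calls, CNV segmentation, and a fusion list from
any fusion-detection tool — and want a fast, deterministic, explainable
triage with plots, census-role annotation, and protein-domain context.

## The classification rule

For a fusion with 5′ partner gene *A* and 3′ partner gene *B*, build the
padded search windows

```
W_A = [start(A) − p, end(A) + p],   W_B = [start(B) − p, end(B) + p]
```

with padding *p* = 50 kb by default. Using only records from the
fusion's own sample:

* **SV evidence** — any breakend (chrom, pos) of any call falling inside
  W_A or W_B (rule `either`, the default; stricter `both` and `linked`
  rules require breakends in both windows, or a single call joining
  them);
* **CNV evidence** — any segment overlapping W_A or W_B with
  |segmean| ≥ τ, where segmean is the log₂(tumor/normal) ratio and
  τ = 0.2 by default.

```
status = Driver  ⇔  SV evidence ≠ ∅  ∧  CNV evidence ≠ ∅
```

Everything else is a Passenger. The verdict comes with an evidence
object (the mapping breakends and segments), an SV/CNV co-occurrence
correlation (per-bin breakend counts vs. length-weighted mean segmean,
Pearson's r over 10 kb bins), cancer-census roles for both partners, and
SVG/PNG/PDF plots of the evidence and the fused protein's domain
architecture.

## Worked example

`examples/classify_simulated_cohort.py` generates a synthetic cohort
(50 fusions across 4 samples, 40 % planted drivers) and triages it:

```
planted labels:  {'Driver': 20, 'Passenger': 30}
called labels:   {'Driver': 20, 'Passenger': 30}
agreement:       50/50 fusions

first three driver calls (fusion, sample, SV classes, CNV direction):
  G0149-G0181  S04  ['translocation']  5'=loss 3'=none
  G0138-G0142  S04  ['duplication']  5'=none 3'=gain
  G0047-G0011  S04  ['deletion']  5'=none 3'=gain
```

Every planted driver is recovered and no passenger is promoted: at zero
simulated noise-dropout the conjunction rule is exact by construction.
Each driver line shows which rearrangement class supplied the breakend
and whether the partner loci gained or lost copy number.
`examples/correlation_and_plots.py` and `examples/annotate_fusion_roles.py`
demonstrate the correlation, plotting, and annotation layers; for
instance the census/domain example prints

```
CUX1-RET: 5'=TSG, 3'=oncogene, oncogenic partner: True
  3' RET cadherin [29-152]: lost
  3' RET kinase [724-1005]: retained
```

— the retained intact kinase domain downstream of a 3′ breakpoint is the
classic architecture of an activating kinase fusion.

The same operations are available from a shell:

```bash
fusiontriage simulate --seed 7 --out-dir sim/
fusiontriage classify --fusions sim/fusions.tsv --sv sim/sv.tsv \
    --cnv sim/cnv.tsv --genes sim/genes.tsv --census sim/census.tsv -o report.tsv
fusiontriage plot --fusion G0149-G0181 --report report.tsv --sv sim/sv.tsv \
    --cnv sim/cnv.tsv --genes sim/genes.tsv --domains sim/domains.tsv --out-dir plots/
```

## Input formats

* **CNV segmentation** — 6 columns, in order: sample ID, chromosome,
  start, end, probe field, segmean (log₂ ratio). 1-based closed
  coordinates (SEG convention); `--bed` shifts 0-based starts.
* **SV calls** — 8 columns: sample, chrom1, pos1, strand1, chrom2, pos2,
  strand2, svclass ∈ {duplication, deletion, inversion, insertion,
  translocation}.
* **Fusions** — one `GENE5-GENE3` per line, or TSV with
  gene5/gene3/sample_id/breakpoints.
* **Gene models, census, domains** — headered TSV lookups.

All readers take TSV or CSV, tolerate an optional header row, and accept
gzip-compressed files. Chromosome names are canonicalized (`chr7` → `7`,
`MT` → `M`) so mixed-dialect inputs overlap correctly.

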