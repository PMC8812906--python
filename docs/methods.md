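# Methods

## The model

`fusiontriage` operationalizes a simple biological premise: a fusion
gene that drives a cancer is created by a genomic rearrangement, and
rearrangement leaves two independent, orthogonal footprints near the
partner loci — structural-variant breakends, and a step in the
copy-number profile. A candidate fusion supported by both footprints in
its own sample is called **Driver**; one lacking either footprint is a
**Passenger**. The rule is a hard conjunction, not a score: the output
is a binary label plus the evidence that produced it, which keeps every
verdict auditable (contrast with rank-based prioritizers, which trade
auditability for ordering).

The premise has known failure modes, stated up front: fusions created
by perfectly balanced rearrangements can lack a CNV footprint and will
be under-called; conversely, a fusion call that coincidentally sits in
a rearranged, dosage-altered region will be over-called. The padding
and threshold parameters below control where those errors land.

## Parameters that matter

| parameter | unit | default | rationale |
|---|---|---|---|
| `padding_bp` | bp | 50 000 | fusion breakpoints frequently fall in introns or flanking regulatory DNA outside the annotated gene span; 50 kb covers typical breakpoint scatter without swallowing neighboring loci |
| `cnv_abs_threshold` | log₂ ratio | 0.2 | a common single-copy-sensitivity cutoff for segmented log ratios; raising it trades recall for precision. Segments with segmean exactly 0 never count, even at threshold 0 — no dosage change is no evidence |
| `sv_rule` | — | `either` | a breakend in either partner window counts. `both` requires breakends at both partners; `linked` requires one call joining the two windows. On any input, hits(linked) ⊆ hits(both) ⊆ hits(either) |
| `sample_scoped` | — | true | evidence must come from the fusion's own sample; pooling across samples is available but conflates recurrence with support |
| `bin_size_bp` (correlation) | bp | 10 000 | resolves a 50 kb-padded gene window into ≳10 bins, enough for a meaningful r without empty-bin dominance |

Two monotonicity guarantees follow from the definitions and are enforced
by tests: enlarging `padding_bp` never demotes a Driver, and raising
`cnv_abs_threshold` never promotes a Passenger.

## Coordinates and formats

All genomic coordinates are 1-based, fully closed (the SEG convention),
and overlap is closed-interval overlap: a breakend sitting exactly on a
window boundary counts as mapping. BED-derived inputs (0-based starts)
are shifted by +1 on read via the `bed` option. Chromosome names are
canonicalized by stripping a `chr` prefix and mapping `MT` to `M`;
canonicalization is idempotent. Intrachromosomal SV calls are normalized
so pos1 ≤ pos2 with strands travelling alongside. The segmean column is
interpreted as log₂(tumor/normal) and never re-transformed; it may
encode subclonal fractional states, which changes nothing in the
overlap logic. The interval engine is backed by one `intervaltree` per
chromosome with the +1 end-shift applied at the boundary, and unknown
chromosomes return empty results rather than erroring, so calls on
unplaced contigs cannot abort a run.

## The correlation coefficient

"Correlation between the mapping SV and CNV profile" is made computable
by an explicit, versioned definition (written into every result's
metadata): tile both padded partner windows into fixed-width bins; per
bin, x = the number of distinct evidence breakends in the bin and y =
the length-weighted mean segmean of all segments covering the bin (all
segments — the dosage *profile* is not thresholded the way *evidence*
is); r = Pearson's product-moment correlation of (x, y) over the
informative bins, i.e. those with non-zero CNV coverage. Bins without
dosage measurements are excluded, not imputed as zero. Overlapping
same-chromosome partner windows are tiled independently rather than
merged, keeping the per-partner signals symmetric. Fewer than 3
informative bins returns `too_few_bins`; a constant signal returns
`zero_variance`; neither is ever coerced to r = 0. Spearman's rank
correlation is available as an alternative estimator. Note that a clean
driver with one planted breakend and one covering segment legitimately
yields `zero_variance` — an undefined r on flat signals is the honest
answer.

## Annotation

Census lookup is a pure, case-insensitive exact-symbol match against a
user-supplied table with the closed role vocabulary {oncogene, TSG,
oncogene+TSG, fusion, unknown}; the bundled test census is a synthetic
mock, not COSMIC data (which cannot be redistributed). Domain retention
operates purely in protein coordinates: with a 5′ breakpoint b, domains
ending at or before b are retained, those starting after b are lost,
and spanning domains are truncated; the 3′ partner mirrors this
(C-terminal side retained). Genomic-to-protein breakpoint conversion is
out of scope — it requires transcript models — so callers supply
amino-acid breakpoints or get both full tracks annotated `n/a`.

## The synthetic-data generator

The generator emulates the cohort structure the method assumes: genes
placed without overlap on a small multi-chromosome genome (defaults:
200 genes of 5–200 kb on five 10 Mb chromosomes), 50 fusion candidates
across 4 samples with a 40 % driver fraction, 100 background SV calls
and 50 background CNV segments with segmean ~ N(0, 0.05). Each planted
driver receives one SV call with a breakend inside a partner gene body
and one CNV segment overlapping a partner with |segmean| drawn from
[0.4, 1.2] (random sign), both in the fusion's sample.

Recovery is made *exact rather than probabilistic* by two constructive
guarantees: partner genes of different fusions are kept far enough
apart (> padding + maximum planted-segment flank) that one fusion's
planted evidence cannot reach another's window, and background records
are rejection-sampled away from every partner's padded window. This
also makes the corruption operations surgical: dropping or weakening
one driver's planted rows flips exactly that driver and nothing else.
An `evidence_dropout` probability removes one evidence type from a
planted driver to create realistic misses, and a `hard_negatives` mode
plants SV-only and CNV-only near-misses on passengers to exercise the
conjunction.

What the generator deliberately does not model — and what passing tests
therefore do not demonstrate about real data: breakpoint microhomology,
read-level noise, segmentation oversplitting, clustered rearrangements
(chromothripsis), gene-dense loci where windows of unrelated genes
overlap, and caller-specific fusion artifacts. On real cohorts the
clean separation between drivers and passengers will blur in proportion
to those effects.

## Numerical and design choices

* Pearson's r is delegated to `scipy.stats`; the test suite checks it
  against the explicit covariance formula at 1e-10, and the near-constant
  input warning is suppressed because sparse breakend signals are
  legitimately near-constant.
* Report serialization writes segmean with `repr`, the shortest exact
  float representation, so parse → write → parse is value-stable.
* SVG output is rendered with a fixed hash salt and no timestamp
  metadata, making re-renders byte-identical; SVG is the canonical
  format for determinism checks, PNG/PDF are conveniences.
* Unresolvable partner symbols demote the fusion to Passenger with an
  `unresolved` flag and a logged warning instead of raising: one stale
  symbol must not kill a cohort run.
* Duplicate gene-model symbols are an error (the coordinate authority
  must be unambiguous); duplicate census symbols keep the last record
  with a warning (annotation is advisory).
* Problem sizes in the test and acceptance runs (500-interval oracle
  comparisons, 100 random classifier instances, the 50-fusion default
  cohort) were chosen as the smallest sizes at which the checked
  properties are non-trivial; all complete in seconds.

## Known limitations

The triage is per-sample and binary: it does not rank drivers, model
recurrence across a cohort, or estimate a false-discovery rate. SV input
is restricted to the 8-column breakend-pair table (no VCF), and no
fusion-caller-specific adapters are provided. The correlation definition
is a package convention — other tools computing "an SV/CNV correlation"
need not agree with it, which is why every result carries its defining
metadata.
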