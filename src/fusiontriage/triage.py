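"""Driver/passenger triage of candidate fusion genes.

The classification rule is a conjunction over orthogonal evidence: a
fusion is called **Driver** when, within padded windows around both
partner genes, at least one SV breakend maps in *and* at least one CNV
segment with a meaningful dosage change maps in; otherwise it is a
**Passenger**. The rationale is that genuine fusion formation is a
genomic event and should leave both a rearrangement footprint (the
breakends) and a dosage footprint (a copy-number step) at the loci
involved, while artifactual or transcriptional chimeras leave neither.

Three SV mapping rules of increasing stringency are offered:

``either``
    any breakend inside either partner's padded window counts (default);
``both``
    evidence counts only when each partner window holds at least one
    breakend;
``linked``
    only calls with one breakend in the 5' window and the other in the
    3' window count — the rearrangement must physically join the loci.

On any input, the hit sets are nested: linked ⊆ both ⊆ either.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

from .errors import ValidationError
from .intervals import GenomicInterval, IntervalIndex, build_index
from .records import CensusRecord, CNVSegment, FusionCandidate, GeneModel, SVCall

logger = logging.getLogger(__name__)

SV_RULES = ("either", "both", "linked")


@dataclass
class TriageConfig:
    """Tunable parameters of the triage.

    padding_bp
        Flank added to each side of each partner gene when searching for
        evidence; fusion breakpoints often fall in introns or regulatory
        flanks outside the annotated span. Default 50 kb.
    cnv_abs_threshold
        Minimum |segmean| (log2 ratio) for a segment to count as a dosage
        change. Default 0.2, a common gain/loss cutoff.
    sv_rule
        One of ``either`` / ``both`` / ``linked`` (see module docstring).
    sample_scoped
        When True (default) only SV/CNV records whose sample matches the
        fusion's sample are evidence; fusions without a sample use the
        full pool, with a warning.
    """

    padding_bp: int = 50_000
    cnv_abs_threshold: float = 0.2
    sv_rule: str = "either"
    sample_scoped: bool = True

    def __post_init__(self) -> None:
        if self.padding_bp < 0:
            raise ValidationError(f"padding_bp must be >= 0, got {self.padding_bp}")
        if self.cnv_abs_threshold < 0:
            raise ValidationError(
                f"cnv_abs_threshold must be >= 0, got {self.cnv_abs_threshold}"
            )
        if self.sv_rule not in SV_RULES:
            raise ValidationError(
                f"sv_rule must be one of {SV_RULES}, got {self.sv_rule!r}"
            )


class SVHit(NamedTuple):
    """One mapping breakend: which call, which partner window, which end."""

    call: SVCall
    partner: int  # 5 or 3
    breakend: int  # 1 or 2


class CNVHit(NamedTuple):
    """One mapping CNV segment with its overlap extent and direction."""

    segment: CNVSegment
    partner: int  # 5 or 3
    overlap_bp: int
    direction: str  # 'gain' or 'loss'


@dataclass
class EvidenceBundle:
    """The SV and CNV evidence behind one verdict."""

    sv_hits: list[SVHit] = field(default_factory=list)
    cnv_hits: list[CNVHit] = field(default_factory=list)
    region5: GenomicInterval | None = None
    region3: GenomicInterval | None = None


@dataclass
class DriverCall:
    """Verdict plus evidence for one fusion candidate."""

    fusion: FusionCandidate
    status: str  # 'Driver' or 'Passenger'
    evidence: EvidenceBundle
    sv_classes: set[str] = field(default_factory=set)
    cnv_direction_5: str = "none"
    cnv_direction_3: str = "none"
    correlation_r: float | None = None
    role_5: str = "unknown"
    role_3: str = "unknown"
    unresolved: bool = False


def resolve_regions(
    fusion: FusionCandidate,
    genes: dict[str, GeneModel],
    cfg: TriageConfig,
) -> tuple[GenomicInterval | None, GenomicInterval | None]:
    """Padded search windows for the two partner loci.

    Each window is the gene span widened by ``cfg.padding_bp`` on both
    sides, floored at coordinate 1. A partner symbol absent from the gene
    models yields ``None`` for its window; the caller marks the fusion
    unresolved rather than raising.
    """
    regions: list[GenomicInterval | None] = []
    for which, symbol in ((5, fusion.gene5), (3, fusion.gene3)):
        gene = genes.get(symbol.casefold())
        if gene is None:
            logger.warning(
                "fusion %s: %d' partner %r not in gene models; cannot resolve",
                fusion.fusion_id,
                which,
                symbol,
            )
            regions.append(None)
            continue
        regions.append(
            GenomicInterval(
                chrom=gene.chrom,
                start=max(1, gene.start - cfg.padding_bp),
                end=gene.end + cfg.padding_bp,
                payload=gene,
            )
        )
    return regions[0], regions[1]


def build_sv_breakend_index(calls: Sequence[SVCall]) -> IntervalIndex:
    """Index every breakend as a 1-bp interval with (call, end) payload."""
    points = []
    for call in calls:
        for which in (1, 2):
            chrom, pos = call.breakend(which)
            points.append(GenomicInterval(chrom, pos, pos, payload=(call, which)))
    return build_index(points)


def build_cnv_index(segments: Sequence[CNVSegment]) -> IntervalIndex:
    """Index CNV segments by their genomic span."""
    return build_index(
        [GenomicInterval(s.chrom, s.start, s.end, payload=s) for s in segments]
    )


def collect_sv_evidence(
    fusion: FusionCandidate,
    regions: tuple[GenomicInterval | None, GenomicInterval | None],
    sv_index: IntervalIndex,
    cfg: TriageConfig,
) -> list[SVHit]:
    """Breakends mapping into the partner windows under ``cfg.sv_rule``."""
    region5, region3 = regions
    hits: list[SVHit] = []
    for partner, region in ((5, region5), (3, region3)):
        if region is None:
            continue
        for iv in sv_index.query(region.chrom, region.start, region.end):
            call, which = iv.payload
            hits.append(SVHit(call, partner, which))

    if cfg.sv_rule == "either" or not hits:
        return hits
    partners_hit = {h.partner for h in hits}
    if cfg.sv_rule == "both":
        return hits if partners_hit == {5, 3} else []
    # linked: keep hits only from calls joining the two windows
    by_call: dict[int, set[tuple[int, int]]] = {}
    call_of: dict[int, SVCall] = {}
    for h in hits:
        by_call.setdefault(id(h.call), set()).add((h.partner, h.breakend))
        call_of[id(h.call)] = h.call
    linked_ids = set()
    for cid, ends in by_call.items():
        for p5, b5 in ends:
            if p5 != 5:
                continue
            if any(p == 3 and b != b5 for p, b in ends):
                linked_ids.add(cid)
                break
    return [h for h in hits if id(h.call) in linked_ids]


def collect_cnv_evidence(
    fusion: FusionCandidate,
    regions: tuple[GenomicInterval | None, GenomicInterval | None],
    cnv_index: IntervalIndex,
    cfg: TriageConfig,
) -> list[CNVHit]:
    """Segments overlapping a partner window with |segmean| past threshold.

    A segmean of exactly 0 never counts (no dosage change), even at
    threshold 0. Overlap length is computed on closed intervals.
    """
    hits: list[CNVHit] = []
    for partner, region in ((5, regions[0]), (3, regions[1])):
        if region is None:
            continue
        for iv in cnv_index.query(region.chrom, region.start, region.end):
            seg: CNVSegment = iv.payload
            if seg.segmean == 0 or abs(seg.segmean) < cfg.cnv_abs_threshold:
                continue
            overlap = min(seg.end, region.end) - max(seg.start, region.start) + 1
            hits.append(CNVHit(seg, partner, overlap, seg.direction))
    return hits


def _aggregate_direction(hits: Iterable[CNVHit], partner: int) -> str:
    dirs = {h.direction for h in hits if h.partner == partner}
    if not dirs:
        return "none"
    if dirs == {"gain"}:
        return "gain"
    if dirs == {"loss"}:
        return "loss"
    return "mixed"


def classify_fusion(
    fusion: FusionCandidate,
    sv_hits: list[SVHit],
    cnv_hits: list[CNVHit],
    regions: tuple[GenomicInterval | None, GenomicInterval | None] = (None, None),
    correlation_r: float | None = None,
    role_5: str = "unknown",
    role_3: str = "unknown",
    unresolved: bool = False,
) -> DriverCall:
    """Apply the conjunction rule to collected evidence.

    Driver ⇔ at least one SV hit AND at least one CNV hit; an
    unresolved fusion (partner absent from the gene models) is always a
    Passenger.
    """
    status = "Driver" if (sv_hits and cnv_hits and not unresolved) else "Passenger"
    return DriverCall(
        fusion=fusion,
        status=status,
        evidence=EvidenceBundle(
            sv_hits=list(sv_hits),
            cnv_hits=list(cnv_hits),
            region5=regions[0],
            region3=regions[1],
        ),
        sv_classes={h.call.svclass for h in sv_hits},
        cnv_direction_5=_aggregate_direction(cnv_hits, 5),
        cnv_direction_3=_aggregate_direction(cnv_hits, 3),
        correlation_r=correlation_r,
        role_5=role_5,
        role_3=role_3,
        unresolved=unresolved,
    )


def _census_role(census: dict[str, CensusRecord] | None, symbol: str) -> str:
    if not census:
        return "unknown"
    rec = census.get(symbol.casefold())
    return rec.role if rec is not None else "unknown"


def classify_all(
    fusions: Sequence[FusionCandidate],
    sv_calls: Sequence[SVCall],
    cnv_segments: Sequence[CNVSegment],
    genes: dict[str, GeneModel],
    census: dict[str, CensusRecord] | None = None,
    cfg: TriageConfig | None = None,
    compute_correlation: bool = True,
    bin_size_bp: int = 10_000,
) -> list[DriverCall]:
    """Classify every fusion, in input order, deterministically.

    With ``sample_scoped`` (default) evidence is drawn only from records
    whose sample matches the fusion's; a fusion without a sample id falls
    back to the pooled records with a warning.
    """
    from .correlation import driver_correlation  # deferred: avoids import cycle

    if cfg is None:
        cfg = TriageConfig()

    def _pools(records):
        by_sample: dict[str | None, list] = {None: list(records)}
        if cfg.sample_scoped:
            for rec in records:
                by_sample.setdefault(rec.sample_id, []).append(rec)
        return by_sample

    sv_pools = _pools(sv_calls)
    cnv_pools = _pools(cnv_segments)
    sv_indexes: dict[str | None, IntervalIndex] = {}
    cnv_indexes: dict[str | None, IntervalIndex] = {}

    calls: list[DriverCall] = []
    for fusion in fusions:
        key: str | None = None
        if cfg.sample_scoped:
            if fusion.sample_id is None:
                logger.warning(
                    "fusion %s has no sample id; using the pooled SV/CNV records",
                    fusion.fusion_id,
                )
            else:
                key = fusion.sample_id
        if key not in sv_indexes:
            sv_indexes[key] = build_sv_breakend_index(sv_pools.get(key, []))
            cnv_indexes[key] = build_cnv_index(cnv_pools.get(key, []))

        regions = resolve_regions(fusion, genes, cfg)
        unresolved = regions[0] is None or regions[1] is None
        sv_hits = collect_sv_evidence(fusion, regions, sv_indexes[key], cfg)
        cnv_hits = collect_cnv_evidence(fusion, regions, cnv_indexes[key], cfg)

        correlation_r = None
        if compute_correlation and not unresolved:
            result = driver_correlation(
                fusion, regions, sv_hits, cnv_pools.get(key, []), bin_size_bp
            )
            correlation_r = result.r if result.reason == "ok" else None

        calls.append(
            classify_fusion(
                fusion,
                sv_hits,
                cnv_hits,
                regions=regions,
                correlation_r=correlation_r,
                role_5=_census_role(census, fusion.gene5),
                role_3=_census_role(census, fusion.gene3),
                unresolved=unresolved,
            )
        )
    return calls
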