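"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately naive — linear scans, per-base-pair
averaging, the textbook correlation formula — and shares no code with
the indexed/vectorized implementation paths it checks.
"""

from __future__ import annotations

import math

from fusiontriage.records import CNVSegment, FusionCandidate, GeneModel, SVCall
from fusiontriage.triage import TriageConfig


def brute_overlaps(intervals, chrom, start, end):
    """All intervals overlapping the closed query, by the definition."""
    return [
        iv
        for iv in intervals
        if iv.chrom == chrom and iv.start <= end and start <= iv.end
    ]


def pearson_direct(x, y):
    """Textbook product-moment correlation: cov(x,y) / (sigma_x sigma_y)."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y))
    vx = sum((a - mx) ** 2 for a in x)
    vy = sum((b - my) ** 2 for b in y)
    return cov / math.sqrt(vx * vy)


def _regions(fusion: FusionCandidate, genes: dict[str, GeneModel], cfg: TriageConfig):
    out = []
    for symbol in (fusion.gene5, fusion.gene3):
        gene = genes.get(symbol.casefold())
        if gene is None:
            out.append(None)
        else:
            out.append(
                (gene.chrom, max(1, gene.start - cfg.padding_bp), gene.end + cfg.padding_bp)
            )
    return out


def _in_region(region, chrom, pos):
    return region is not None and region[0] == chrom and region[1] <= pos <= region[2]


def brute_classify(
    fusions: list[FusionCandidate],
    sv_calls: list[SVCall],
    cnv_segments: list[CNVSegment],
    genes: dict[str, GeneModel],
    cfg: TriageConfig,
):
    """No-index reference classifier.

    Returns, per fusion, a dict with the status and hit identity sets:
    SV hits as frozenset of (call index, partner, breakend) and CNV hits
    as frozenset of (segment index, partner, overlap_bp, direction).
    """
    results = []
    for fusion in fusions:
        if cfg.sample_scoped and fusion.sample_id is not None:
            svs = [(i, c) for i, c in enumerate(sv_calls) if c.sample_id == fusion.sample_id]
            cnvs = [
                (i, s) for i, s in enumerate(cnv_segments) if s.sample_id == fusion.sample_id
            ]
        else:
            svs = list(enumerate(sv_calls))
            cnvs = list(enumerate(cnv_segments))
        region5, region3 = _regions(fusion, genes, cfg)
        unresolved = region5 is None or region3 is None

        sv_hits = set()
        for i, call in svs:
            for partner, region in ((5, region5), (3, region3)):
                for which in (1, 2):
                    chrom, pos = call.breakend(which)
                    if _in_region(region, chrom, pos):
                        sv_hits.add((i, partner, which))
        if cfg.sv_rule == "both":
            partners = {p for _, p, _ in sv_hits}
            if partners != {5, 3}:
                sv_hits = set()
        elif cfg.sv_rule == "linked":
            linked_calls = set()
            for i, _p, _b in sv_hits:
                fives = {b for j, p, b in sv_hits if j == i and p == 5}
                threes = {b for j, p, b in sv_hits if j == i and p == 3}
                if any(b5 != b3 for b5 in fives for b3 in threes):
                    linked_calls.add(i)
            sv_hits = {(i, p, b) for i, p, b in sv_hits if i in linked_calls}

        cnv_hits = set()
        for i, seg in cnvs:
            if seg.segmean == 0 or abs(seg.segmean) < cfg.cnv_abs_threshold:
                continue
            for partner, region in ((5, region5), (3, region3)):
                if region is None or seg.chrom != region[0]:
                    continue
                if seg.start <= region[2] and region[1] <= seg.end:
                    overlap = min(seg.end, region[2]) - max(seg.start, region[1]) + 1
                    cnv_hits.add((i, partner, overlap, seg.direction))

        status = "Driver" if (sv_hits and cnv_hits and not unresolved) else "Passenger"
        results.append(
            {"status": status, "sv_hits": frozenset(sv_hits), "cnv_hits": frozenset(cnv_hits)}
        )
    return results


def hits_as_ids(call, sv_calls, cnv_segments):
    """Project a DriverCall's hits onto input indices for oracle comparison."""
    sv_pos = {id(c): i for i, c in enumerate(sv_calls)}
    cnv_pos = {id(s): i for i, s in enumerate(cnv_segments)}
    sv = frozenset(
        (sv_pos[id(h.call)], h.partner, h.breakend) for h in call.evidence.sv_hits
    )
    cnv = frozenset(
        (cnv_pos[id(h.segment)], h.partner, h.overlap_bp, h.direction)
        for h in call.evidence.cnv_hits
    )
    return sv, cnv
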