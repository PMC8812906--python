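"""Correlation between the SV and CNV signals over a fusion's loci.

The two "profiles" are made comparable by tiling both padded partner
windows into fixed-width bins (default 10 kb) and measuring, per bin,

* ``x`` — the number of evidence breakends whose position falls in the
  bin, and
* ``y`` — the length-weighted mean segmean of the CNV segments covering
  the bin (all segments, regardless of the evidence threshold: this is
  the dosage profile, not the evidence call).

``r`` is then the Pearson product-moment correlation of (x, y) over the
*informative* bins — those with non-zero CNV coverage. Bins with no
dosage measurement carry no information about co-occurrence and are
excluded rather than imputed as zero. When fewer than 3 informative bins
exist, or either signal is constant, the result is flagged not-computable
with a reason code; it is never silently coerced to 0.

Same-chromosome partner windows that overlap are *not* merged: each
window is tiled independently, so bins may double-cover a region. This
keeps the per-partner signals symmetric and the binning deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import ValidationError
from .intervals import GenomicInterval
from .records import CNVSegment, FusionCandidate
from .triage import SVHit

#: Definition fingerprint written into output metadata so results are
#: self-describing (the operands of r are a package convention).
DEFINITION = "binned breakend count vs length-weighted mean segmean; informative bins"


@dataclass
class CorrelationResult:
    """Outcome of the binned SV/CNV correlation for one fusion."""

    fusion_id: str
    bin_size_bp: int
    n_bins_total: int
    n_bins_informative: int
    r: float | None
    reason: str  # 'ok', 'too_few_bins' or 'zero_variance'
    method: str = "pearson"
    definition: str = DEFINITION
    x: np.ndarray | None = field(default=None, repr=False)
    y: np.ndarray | None = field(default=None, repr=False)


def bin_regions(
    region5: GenomicInterval | None,
    region3: GenomicInterval | None,
    bin_size_bp: int = 10_000,
) -> list[GenomicInterval]:
    """Tile each partner window into consecutive closed bins.

    Bins are laid left-to-right with width ``bin_size_bp``; the last bin
    of each window is truncated at the window end. The 5' window's bins
    come first, then the 3' window's; the total covered length equals
    the sum of the window widths.
    """
    if bin_size_bp < 1:
        raise ValidationError(f"bin_size_bp must be >= 1, got {bin_size_bp}")
    bins: list[GenomicInterval] = []
    for partner, region in ((5, region5), (3, region3)):
        if region is None:
            continue
        pos = region.start
        while pos <= region.end:
            bins.append(
                GenomicInterval(
                    region.chrom,
                    pos,
                    min(pos + bin_size_bp - 1, region.end),
                    payload=partner,
                )
            )
            pos += bin_size_bp
    return bins


def sv_signal(bins: list[GenomicInterval], sv_hits: list[SVHit]) -> np.ndarray:
    """Per-bin count of distinct evidence breakends.

    A breakend referenced by several hit entries (e.g. one call mapping
    both partner windows) is counted once per bin containing it; bins
    from overlapping windows may each contain the same breakend.
    """
    points: set[tuple[int, int, str, int]] = set()
    for h in sv_hits:
        chrom, pos = h.call.breakend(h.breakend)
        points.add((id(h.call), h.breakend, chrom, pos))
    x = np.zeros(len(bins), dtype=float)
    for i, b in enumerate(bins):
        x[i] = sum(
            1 for _, _, chrom, pos in points if chrom == b.chrom and b.start <= pos <= b.end
        )
    return x


def cnv_signal(
    bins: list[GenomicInterval], cnv_segments: list[CNVSegment]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin length-weighted mean segmean and a coverage mask.

    Returns ``(y, informative)`` where ``informative[i]`` is True when at
    least one segment overlaps bin i. Weights are the closed-interval
    overlap lengths; overlapping segments within one bin average by
    their covered lengths.
    """
    y = np.zeros(len(bins), dtype=float)
    informative = np.zeros(len(bins), dtype=bool)
    for i, b in enumerate(bins):
        wsum = 0.0
        vsum = 0.0
        for seg in cnv_segments:
            if seg.chrom != b.chrom or seg.start > b.end or b.start > seg.end:
                continue
            w = min(seg.end, b.end) - max(seg.start, b.start) + 1
            wsum += w
            vsum += w * seg.segmean
        if wsum > 0:
            y[i] = vsum / wsum
            informative[i] = True
    return y, informative


def driver_correlation(
    fusion: FusionCandidate,
    regions: tuple[GenomicInterval | None, GenomicInterval | None],
    sv_hits: list[SVHit],
    cnv_segments: list[CNVSegment],
    bin_size_bp: int = 10_000,
    method: str = "pearson",
) -> CorrelationResult:
    """Correlate the binned SV and CNV signals over the fusion's windows.

    Not-computable outcomes are returned as reason codes — never as an
    exception and never as r = 0.
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"method must be 'pearson' or 'spearman', got {method!r}")
    bins = bin_regions(regions[0], regions[1], bin_size_bp)
    x_all = sv_signal(bins, sv_hits)
    y_all, informative = cnv_signal(bins, cnv_segments)
    x = x_all[informative]
    y = y_all[informative]

    def _result(r, reason):
        return CorrelationResult(
            fusion_id=fusion.fusion_id,
            bin_size_bp=bin_size_bp,
            n_bins_total=len(bins),
            n_bins_informative=int(informative.sum()),
            r=r,
            reason=reason,
            method=method,
            x=x,
            y=y,
        )

    if x.size < 3:
        return _result(None, "too_few_bins")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return _result(None, "zero_variance")
    with warnings.catch_warnings():
        # sparse breakend signals are legitimately near-constant
        warnings.simplefilter("ignore", stats.NearConstantInputWarning)
        if method == "pearson":
            r = float(stats.pearsonr(x, y).statistic)
        else:
            r = float(stats.spearmanr(x, y).statistic)
    return _result(r, "ok")
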