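"""Evidence, domain and correlation plots.

SVG is the canonical output format: files are written with a fixed
hash salt and no timestamp metadata, so re-rendering the same inputs
produces byte-identical text (diffable in review and testable for
determinism). PNG and PDF are convenience formats.

No plotting function mutates its inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .annotation import FusionDomainLayout
from .correlation import CorrelationResult
from .errors import ValidationError
from .records import CNVSegment
from .triage import DriverCall

PLOT_FORMATS = ("png", "svg", "pdf")

#: fixed per-class colors so legends are stable across runs
SVCLASS_COLORS = {
    "duplication": "#1b9e77",
    "deletion": "#d95f02",
    "inversion": "#7570b3",
    "insertion": "#e7298a",
    "translocation": "#66a61e",
}

_HASHSALT = {"svg.hashsalt": "fusiontriage"}


@dataclass
class PlotSpec:
    """Where and how to render one figure."""

    path: str
    format: str = "svg"
    width: float = 9.0
    height: float = 5.5
    dpi: int = 100
    title: str | None = None

    def __post_init__(self) -> None:
        if self.format not in PLOT_FORMATS:
            raise ValidationError(
                f"format must be one of {PLOT_FORMATS}, got {self.format!r}"
            )
        if self.dpi < 72:
            raise ValidationError(f"dpi must be >= 72, got {self.dpi}")


def _save(fig, spec: PlotSpec) -> str:
    metadata = {"Date": None} if spec.format == "svg" else None
    with plt.rc_context(_HASHSALT):
        fig.savefig(
            spec.path, format=spec.format, dpi=spec.dpi, metadata=metadata,
            bbox_inches="tight",
        )
    plt.close(fig)
    return spec.path


def render_driver_plot(
    call: DriverCall, cnv_segments: Sequence[CNVSegment], spec: PlotSpec
) -> str:
    """One panel per partner locus: CNV step track plus SV breakend glyphs.

    The padded gene window is the x-range; the gene body is shaded. The
    verdict appears in the title. Raises for an unresolved fusion (its
    partner loci are unknown — check the gene models).
    """
    ev = call.evidence
    if ev.region5 is None and ev.region3 is None:
        raise ValidationError(
            f"fusion {call.fusion.fusion_id} is unresolved; check the gene models"
        )
    panels = [(5, ev.region5), (3, ev.region3)]
    panels = [(p, r) for p, r in panels if r is not None]

    fig, axes = plt.subplots(
        1, len(panels), figsize=(spec.width, spec.height), squeeze=False
    )
    seen_classes: list[str] = []
    for ax, (partner, region) in zip(axes[0], panels):
        gene = region.payload
        if gene is not None:
            ax.axvspan(gene.start, gene.end, color="#dddddd", zorder=0, label=None)
        # CNV step track over the window
        for seg in cnv_segments:
            if seg.chrom != region.chrom or seg.start > region.end or seg.end < region.start:
                continue
            ax.hlines(
                seg.segmean,
                max(seg.start, region.start),
                min(seg.end, region.end),
                colors="#333333",
                linewidth=2.0,
            )
        ax.axhline(0, color="#999999", linewidth=0.6, linestyle=":")
        # SV breakend glyphs, colored by class
        for h in ev.sv_hits:
            if h.partner != partner:
                continue
            chrom, pos = h.call.breakend(h.breakend)
            ax.axvline(
                pos,
                color=SVCLASS_COLORS[h.call.svclass],
                linewidth=1.2,
                alpha=0.9,
            )
            ax.plot(
                [pos],
                [1.05],
                marker="v",
                color=SVCLASS_COLORS[h.call.svclass],
                markersize=7,
                clip_on=False,
            )
            if h.call.svclass not in seen_classes:
                seen_classes.append(h.call.svclass)
        symbol = gene.symbol if gene is not None else "?"
        ax.set_xlim(region.start, region.end)
        ax.set_ylim(-1.5, 1.5)
        ax.set_title(f"{partner}' partner: {symbol} ({region.chrom})")
        ax.set_xlabel(f"position on chr{region.chrom} (bp)")
        ax.set_ylabel("segmean (log2 ratio)")
    handles = [
        plt.Line2D([], [], color=SVCLASS_COLORS[c], label=c)
        for c in sorted(seen_classes)
    ]
    if handles:
        axes[0][-1].legend(handles=handles, loc="lower right", fontsize=8)
    fig.suptitle(
        spec.title
        or f"{call.fusion.fusion_id} — {call.status} "
        f"({len(ev.sv_hits)} SV, {len(ev.cnv_hits)} CNV hits)"
    )
    return _save(fig, spec)


_STATUS_STYLE = {
    "retained": {"facecolor": "#4c9f70", "hatch": None},
    "truncated": {"facecolor": "#e0b04b", "hatch": "//"},
    "lost": {"facecolor": "#c8c8c8", "hatch": "xx"},
    "n/a": {"facecolor": "#6699cc", "hatch": None},
}


def render_domain_plot(layout: FusionDomainLayout, spec: PlotSpec) -> str | None:
    """Horizontal protein tracks with labeled domain boxes.

    Lost domains are hatched; a supplied breakpoint is drawn as a
    vertical marker. With no domains on either partner the plot is
    skipped (None returned) rather than failing.
    """
    tracks = [
        ("5'", layout.partner5, layout.breakpoint5_aa),
        ("3'", layout.partner3, layout.breakpoint3_aa),
    ]
    if not layout.partner5 and not layout.partner3:
        import logging

        logging.getLogger(__name__).warning(
            "no domains for either partner of %s; skipping domain plot",
            layout.fusion_id,
        )
        return None

    fig, axes = plt.subplots(2, 1, figsize=(spec.width, spec.height), squeeze=False)
    for ax, (label, track, bp) in zip(axes[:, 0], tracks):
        max_aa = max((d.domain.end_aa for d in track), default=100)
        ax.hlines(0.5, 1, max_aa * 1.05, colors="#555555", linewidth=1.5)
        for ds in track:
            style = _STATUS_STYLE[ds.status]
            ax.broken_barh(
                [(ds.domain.start_aa, ds.domain.end_aa - ds.domain.start_aa + 1)],
                (0.3, 0.4),
                facecolors=style["facecolor"],
                hatch=style["hatch"],
                edgecolor="black",
                linewidth=0.8,
            )
            ax.text(
                (ds.domain.start_aa + ds.domain.end_aa) / 2,
                0.82,
                ds.domain.domain_name,
                ha="center",
                fontsize=8,
            )
        if bp is not None:
            ax.axvline(bp, color="red", linewidth=1.4, linestyle="--")
        ax.set_ylim(0, 1.1)
        ax.set_yticks([])
        ax.set_xlabel("amino-acid position")
        ax.set_title(f"{label} partner", fontsize=10, loc="left")
    fig.suptitle(spec.title or f"Domain architecture: {layout.fusion_id}")
    return _save(fig, spec)


def render_correlation_plot(result: CorrelationResult, spec: PlotSpec) -> str:
    """Scatter of per-bin (SV count, segmean) with a least-squares line."""
    if result.reason != "ok":
        raise ValidationError(
            f"correlation for {result.fusion_id} is not computable "
            f"(reason: {result.reason})"
        )
    x = np.asarray(result.x, dtype=float)
    y = np.asarray(result.y, dtype=float)
    fig, ax = plt.subplots(figsize=(spec.width, spec.height))
    ax.scatter(x, y, s=28, color="#2b6ca3", alpha=0.8, edgecolor="black", linewidth=0.4)
    slope, intercept = np.polyfit(x, y, 1)
    grid = np.linspace(x.min(), x.max(), 50)
    ax.plot(grid, slope * grid + intercept, color="#d62728", linewidth=1.4)
    ax.annotate(
        f"r = {result.r:.2f} ({result.method})",
        xy=(0.03, 0.95),
        xycoords="axes fraction",
        fontsize=11,
        va="top",
    )
    ax.set_xlabel(f"SV breakends per {result.bin_size_bp:,} bp bin")
    ax.set_ylabel("mean segmean (log2 ratio)")
    ax.set_title(spec.title or f"SV/CNV co-occurrence: {result.fusion_id}")
    return _save(fig, spec)
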