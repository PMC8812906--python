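"""Cancer-census role lookup and fusion domain architecture.

The census lookup is a pure, case-insensitive exact-symbol match: a
partner absent from the census table gets role ``unknown`` with empty
tumor/mutation lists. A fusion is summarized as having an oncogenic
partner when either partner's role includes ``oncogene``.

Domain retention operates purely in protein (amino-acid) coordinates.
The 5' partner contributes its N-terminal side up to its breakpoint; the
3' partner contributes its C-terminal side from its breakpoint on.
Genomic-to-protein breakpoint conversion is out of scope (it requires
transcript models), so callers supply amino-acid breakpoints directly or
none at all, in which case both partners' full tracks are reported with
status ``n/a``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ValidationError
from .records import CensusRecord, DomainRecord, FusionCandidate


@dataclass
class PartnerRole:
    symbol: str
    role: str = "unknown"
    tumor_types: list[str] = field(default_factory=list)
    mutation_types: list[str] = field(default_factory=list)


@dataclass
class RoleAnnotation:
    """Census roles for both partners of one fusion."""

    fusion_id: str
    partner5: PartnerRole
    partner3: PartnerRole

    @property
    def oncogenic_partner(self) -> bool:
        """True when either partner's role includes 'oncogene'."""
        return "oncogene" in self.partner5.role or "oncogene" in self.partner3.role


@dataclass
class DomainStatus:
    domain: DomainRecord
    status: str  # 'retained', 'lost', 'truncated' or 'n/a'


@dataclass
class FusionDomainLayout:
    """Per-partner domain tracks with retention status."""

    fusion_id: str
    partner5: list[DomainStatus] = field(default_factory=list)
    partner3: list[DomainStatus] = field(default_factory=list)
    breakpoint5_aa: int | None = None
    breakpoint3_aa: int | None = None


def classify_cancer_gene(
    fusion: FusionCandidate, census: dict[str, CensusRecord]
) -> RoleAnnotation:
    """Annotate both partners of ``fusion`` from the census lookup."""

    def _partner(symbol: str) -> PartnerRole:
        rec = census.get(symbol.casefold())
        if rec is None:
            return PartnerRole(symbol=symbol)
        return PartnerRole(
            symbol=symbol,
            role=rec.role,
            tumor_types=list(rec.tumor_types),
            mutation_types=list(rec.mutation_types),
        )

    return RoleAnnotation(
        fusion_id=fusion.fusion_id,
        partner5=_partner(fusion.gene5),
        partner3=_partner(fusion.gene3),
    )


def _status_5prime(d: DomainRecord, bp: int) -> str:
    # N-terminal side retained: domains ending at or before bp survive
    if d.end_aa <= bp:
        return "retained"
    if d.start_aa > bp:
        return "lost"
    return "truncated"


def _status_3prime(d: DomainRecord, bp: int) -> str:
    # C-terminal side retained: domains starting at or after bp survive
    if d.start_aa >= bp:
        return "retained"
    if d.end_aa < bp:
        return "lost"
    return "truncated"


def fusion_domain_layout(
    fusion: FusionCandidate,
    domains: dict[str, list[DomainRecord]],
    breakpoint5_aa: int | None = None,
    breakpoint3_aa: int | None = None,
) -> FusionDomainLayout:
    """Domain tracks for both partners, with retention status.

    Without breakpoints every domain's status is ``n/a`` (a side-by-side
    rendering of the two full proteins). With a breakpoint, each domain
    on that partner is exactly one of retained / lost / truncated.
    """
    for bp in (breakpoint5_aa, breakpoint3_aa):
        if bp is not None and bp < 1:
            raise ValidationError(f"protein breakpoint must be >= 1, got {bp}")

    def _track(symbol: str, bp: int | None, status_fn) -> list[DomainStatus]:
        track = sorted(
            domains.get(symbol.casefold(), []), key=lambda d: (d.start_aa, d.end_aa)
        )
        return [
            DomainStatus(d, "n/a" if bp is None else status_fn(d, bp)) for d in track
        ]

    return FusionDomainLayout(
        fusion_id=fusion.fusion_id,
        partner5=_track(fusion.gene5, breakpoint5_aa, _status_5prime),
        partner3=_track(fusion.gene3, breakpoint3_aa, _status_3prime),
        breakpoint5_aa=breakpoint5_aa,
        breakpoint3_aa=breakpoint3_aa,
    )
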