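"""Domain record types.

All genomic coordinates in this package are 1-based, fully closed
intervals (the SEG convention): a segment [100, 100] covers exactly one
base pair. Chromosome names are canonicalized on construction: a leading
``chr``/``Chr`` prefix is stripped and ``MT`` is mapped to ``M``, so
``chr7``, ``Chr7`` and ``7`` all index the same sequence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ValidationError

#: Closed vocabulary of structural-variant classes.
SV_CLASSES = frozenset(
    {"duplication", "deletion", "inversion", "insertion", "translocation"}
)

#: Closed vocabulary of cancer-census roles.
CENSUS_ROLES = frozenset({"oncogene", "TSG", "oncogene+TSG", "fusion", "unknown"})

_STRANDS = {"+": "+", "-": "-", "−": "-"}  # accept the unicode minus


def canonical_chrom(chrom: str) -> str:
    """Canonicalize a chromosome name.

    Strips a leading ``chr`` (any case), maps ``MT`` to ``M`` and returns
    the bare name. Idempotent: ``canonical_chrom(canonical_chrom(x)) ==
    canonical_chrom(x)``.
    """
    name = str(chrom).strip()
    if name.lower().startswith("chr"):
        name = name[3:]
    if name.upper() == "MT":
        name = "M"
    if not name:
        raise ValidationError(f"empty chromosome name after canonicalization: {chrom!r}")
    return name


def _canonical_strand(strand: str) -> str:
    s = _STRANDS.get(str(strand).strip())
    if s is None:
        raise ValidationError(f"strand must be '+' or '-', got {strand!r}")
    return s


@dataclass
class CNVSegment:
    """One segmented copy-number interval.

    ``segmean`` is the dimensionless log2(tumor/normal) ratio of the
    segment; positive values are gains, negative values losses.
    ``probe_field`` is column 5 of the segmentation table, kept as an
    opaque token (some pipelines emit probe counts, others identifiers).
    """

    sample_id: str
    chrom: str
    start: int
    end: int
    probe_field: str
    segmean: float

    def __post_init__(self) -> None:
        self.chrom = canonical_chrom(self.chrom)
        self.start = int(self.start)
        self.end = int(self.end)
        self.segmean = float(self.segmean)
        self.probe_field = str(self.probe_field)
        if self.start < 1:
            raise ValidationError(f"CNV segment start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValidationError(
                f"CNV segment start {self.start} > end {self.end} "
                f"({self.sample_id} {self.chrom})"
            )
        if not math.isfinite(self.segmean):
            raise ValidationError(f"segmean must be finite, got {self.segmean!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def direction(self) -> str:
        """``gain`` for positive segmean, ``loss`` for negative, ``neutral`` for 0."""
        if self.segmean > 0:
            return "gain"
        if self.segmean < 0:
            return "loss"
        return "neutral"


@dataclass
class SVCall:
    """One structural-variant call: two breakends plus a class.

    Intrachromosomal calls are normalized so that ``pos1 <= pos2`` (the
    strand travels with its position). ``svclass`` is case-folded into the
    closed vocabulary duplication / deletion / inversion / insertion /
    translocation.
    """

    sample_id: str
    chrom1: str
    pos1: int
    strand1: str
    chrom2: str
    pos2: int
    strand2: str
    svclass: str

    def __post_init__(self) -> None:
        self.chrom1 = canonical_chrom(self.chrom1)
        self.chrom2 = canonical_chrom(self.chrom2)
        self.pos1 = int(self.pos1)
        self.pos2 = int(self.pos2)
        self.strand1 = _canonical_strand(self.strand1)
        self.strand2 = _canonical_strand(self.strand2)
        self.svclass = str(self.svclass).strip().lower()
        if self.pos1 < 1 or self.pos2 < 1:
            raise ValidationError(
                f"breakend positions must be >= 1, got {self.pos1}, {self.pos2}"
            )
        if self.svclass not in SV_CLASSES:
            raise ValidationError(
                f"unknown svclass {self.svclass!r}; allowed: "
                + ", ".join(sorted(SV_CLASSES))
            )
        if self.chrom1 == self.chrom2 and self.pos1 > self.pos2:
            self.pos1, self.pos2 = self.pos2, self.pos1
            self.strand1, self.strand2 = self.strand2, self.strand1

    def breakend(self, which: int) -> tuple[str, int]:
        """Return (chrom, pos) for breakend 1 or 2."""
        if which == 1:
            return self.chrom1, self.pos1
        if which == 2:
            return self.chrom2, self.pos2
        raise ValueError(f"breakend index must be 1 or 2, got {which}")


@dataclass
class FusionCandidate:
    """A candidate 5'-3' fusion gene pair from any fusion caller."""

    gene5: str
    gene3: str
    sample_id: str | None = None
    breakpoint5: int | None = None
    breakpoint3: int | None = None
    fusion_id: str = field(default="")

    def __post_init__(self) -> None:
        self.gene5 = str(self.gene5).strip()
        self.gene3 = str(self.gene3).strip()
        if not self.gene5 or not self.gene3:
            raise ValidationError("fusion partner gene symbols must be non-empty")
        self.fusion_id = f"{self.gene5}-{self.gene3}"
        if self.breakpoint5 is not None:
            self.breakpoint5 = int(self.breakpoint5)
        if self.breakpoint3 is not None:
            self.breakpoint3 = int(self.breakpoint3)


@dataclass
class GeneModel:
    """Genomic span of a gene, keyed case-insensitively by symbol."""

    symbol: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        self.symbol = str(self.symbol).strip()
        if not self.symbol:
            raise ValidationError("gene symbol must be non-empty")
        self.chrom = canonical_chrom(self.chrom)
        self.start = int(self.start)
        self.end = int(self.end)
        self.strand = _canonical_strand(self.strand)
        if self.start > self.end:
            raise ValidationError(
                f"gene {self.symbol}: start {self.start} > end {self.end}"
            )

    @property
    def key(self) -> str:
        return self.symbol.casefold()


@dataclass
class CensusRecord:
    """Cancer-census role annotation for one gene."""

    symbol: str
    role: str
    tumor_types: list[str] = field(default_factory=list)
    mutation_types: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.symbol = str(self.symbol).strip()
        if not self.symbol:
            raise ValidationError("census symbol must be non-empty")
        if self.role not in CENSUS_ROLES:
            raise ValidationError(
                f"unknown census role {self.role!r}; allowed: "
                + ", ".join(sorted(CENSUS_ROLES))
            )

    @property
    def key(self) -> str:
        return self.symbol.casefold()


@dataclass
class DomainRecord:
    """One protein domain of a gene, in 1-based amino-acid coordinates."""

    symbol: str
    domain_name: str
    start_aa: int
    end_aa: int
    source_id: str = ""

    def __post_init__(self) -> None:
        self.symbol = str(self.symbol).strip()
        self.start_aa = int(self.start_aa)
        self.end_aa = int(self.end_aa)
        if not (1 <= self.start_aa <= self.end_aa):
            raise ValidationError(
                f"domain {self.domain_name!r} of {self.symbol}: need "
                f"1 <= start_aa <= end_aa, got [{self.start_aa}, {self.end_aa}]"
            )
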