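"""Readers and writers for every tabular format the tool touches.

Supported inputs
----------------
* CNV segmentation: 6 columns in fixed order — sample ID, chromosome,
  start, end, probe field, segmean (log2 tumor/normal ratio). SEG-like,
  1-based closed coordinates.
* SV calls: 8 columns in fixed order — sample, chrom1, pos1, strand1,
  chrom2, pos2, strand2, svclass. BEDPE-like breakend pairs but 1-based.
* Fusion lists: either one ``GENE5-GENE3`` token per line or a TSV with
  columns gene5, gene3 [, sample_id, breakpoint5, breakpoint3].
* Gene models, census and domain tables: headered TSV.

All readers accept a path (gzip-compressed if it ends in ``.gz``) or an
open text stream. A single header row is auto-detected for the CNV and
SV tables: if the first row's coordinate cells are non-numeric it is
treated as a header. Coordinates are 1-based closed; BED-derived input
(0-based half-open starts) can be shifted on read with ``bed=True``.

Malformed rows raise :class:`~fusiontriage.errors.RowParseError` carrying
the 1-based line number; tables with too few columns raise
:class:`~fusiontriage.errors.SchemaError` naming the first missing column.
"""

from __future__ import annotations

import csv
import gzip
import logging
import os
from contextlib import contextmanager
from typing import IO, Iterable, Iterator

from .errors import AmbiguityError, RowParseError, SchemaError, ValidationError
from .records import (
    CensusRecord,
    CNVSegment,
    DomainRecord,
    FusionCandidate,
    GeneModel,
    SVCall,
)

logger = logging.getLogger(__name__)

CNV_COLUMNS = ("sample_id", "chrom", "start", "end", "probe_field", "segmean")
SV_COLUMNS = (
    "sample_id",
    "chrom1",
    "pos1",
    "strand1",
    "chrom2",
    "pos2",
    "strand2",
    "svclass",
)
REPORT_COLUMNS = (
    "fusion_id",
    "sample_id",
    "status",
    "n_sv_hits",
    "sv_classes",
    "n_cnv_hits",
    "cnv_direction_5",
    "cnv_direction_3",
    "correlation_r",
    "role_5",
    "role_3",
)

_MISSING = ("", ".", "NA", "na", "NaN", "None")


@contextmanager
def _open_text(source: str | os.PathLike | IO[str], mode: str = "rt"):
    """Yield a text stream for a path (gzip-aware) or pass a stream through."""
    if hasattr(source, "read") or hasattr(source, "write"):
        yield source  # caller-owned stream; do not close
        return
    path = os.fspath(source)
    opener = gzip.open if path.endswith(".gz") else open
    with opener(path, mode) as fh:  # type: ignore[operator]
        yield fh


def _rows(stream: IO[str], dialect: str) -> Iterator[tuple[int, list[str]]]:
    """Yield (1-based line number, cells) for each non-blank line."""
    if dialect not in ("tsv", "csv"):
        raise ValueError(f"dialect must be 'tsv' or 'csv', got {dialect!r}")
    if dialect == "csv":
        for line_no, cells in enumerate(csv.reader(stream), start=1):
            if cells and any(c.strip() for c in cells):
                yield line_no, [c.strip() for c in cells]
        return
    for line_no, line in enumerate(stream, start=1):
        line = line.rstrip("\n").rstrip("\r")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        cells = line.split("\t") if "\t" in line else line.split()
        yield line_no, [c.strip() for c in cells]


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except (TypeError, ValueError):
        return False


def _check_width(cells: list[str], columns: tuple[str, ...], line_no: int) -> None:
    if len(cells) < len(columns):
        raise SchemaError(
            f"line {line_no}: expected {len(columns)} columns, got {len(cells)}; "
            f"missing column {columns[len(cells)]!r}"
        )


def read_cnv_segments(
    source, dialect: str = "tsv", bed: bool = False
) -> list[CNVSegment]:
    """Read a 6-column CNV segmentation table.

    Parameters
    ----------
    source : path or text stream
    dialect : {'tsv', 'csv'}
    bed : bool
        If True, input starts are treated as 0-based (BED convention) and
        shifted by +1 into the package's 1-based closed coordinates.

    Returns one :class:`CNVSegment` per data row in file order.
    """
    segments: list[CNVSegment] = []
    warned_extra = False
    with _open_text(source) as stream:
        for i, (line_no, cells) in enumerate(_rows(stream, dialect)):
            if i == 0 and len(cells) >= 4 and not (
                _is_number(cells[2]) and _is_number(cells[3])
            ):
                continue  # header row
            _check_width(cells, CNV_COLUMNS, line_no)
            if len(cells) > len(CNV_COLUMNS) and not warned_extra:
                logger.warning(
                    "CNV table has %d columns; ignoring columns beyond %d",
                    len(cells),
                    len(CNV_COLUMNS),
                )
                warned_extra = True
            sample_id, chrom, start, end, probe, segmean = cells[:6]
            if not (_is_number(start) and _is_number(end) and _is_number(segmean)):
                raise RowParseError(
                    f"non-numeric start/end/segmean in {cells[:6]!r}", line_no
                )
            try:
                seg = CNVSegment(
                    sample_id=sample_id,
                    chrom=chrom,
                    start=int(float(start)) + (1 if bed else 0),
                    end=int(float(end)),
                    probe_field=probe,
                    segmean=float(segmean),
                )
            except ValidationError as exc:
                raise ValidationError(f"line {line_no}: {exc}") from exc
            segments.append(seg)
    return segments


def read_sv_calls(source, dialect: str = "tsv") -> list[SVCall]:
    """Read an 8-column SV call table; one :class:`SVCall` per data row."""
    calls: list[SVCall] = []
    warned_extra = False
    with _open_text(source) as stream:
        for i, (line_no, cells) in enumerate(_rows(stream, dialect)):
            if i == 0 and len(cells) >= 6 and not (
                _is_number(cells[2]) and _is_number(cells[5])
            ):
                continue  # header row
            _check_width(cells, SV_COLUMNS, line_no)
            if len(cells) > len(SV_COLUMNS) and not warned_extra:
                logger.warning(
                    "SV table has %d columns; ignoring columns beyond %d",
                    len(cells),
                    len(SV_COLUMNS),
                )
                warned_extra = True
            sample, c1, p1, s1, c2, p2, s2, svclass = cells[:8]
            if not (_is_number(p1) and _is_number(p2)):
                raise RowParseError(f"non-numeric breakend position in {cells[:8]!r}", line_no)
            try:
                call = SVCall(
                    sample_id=sample,
                    chrom1=c1,
                    pos1=int(float(p1)),
                    strand1=s1,
                    chrom2=c2,
                    pos2=int(float(p2)),
                    strand2=s2,
                    svclass=svclass,
                )
            except ValidationError as exc:
                raise ValidationError(f"line {line_no}: {exc}") from exc
            calls.append(call)
    return calls


def read_fusions(source) -> list[FusionCandidate]:
    """Read a fusion-gene list.

    Accepts one ``GENE5-GENE3`` token per line or TSV rows ``gene5 gene3
    [sample_id breakpoint5 breakpoint3]`` (header auto-detected on the
    ``gene5`` column name). A token with more than one ``-`` is ambiguous
    — gene symbols containing the separator must use the TSV form.
    Duplicates are preserved: a caller may report one fusion in several
    samples.
    """
    fusions: list[FusionCandidate] = []
    with _open_text(source) as stream:
        first = True
        for line_no, cells in _rows(stream, "tsv"):
            if first and cells[0].casefold() in ("gene5", "fusion", "fusion_id"):
                first = False
                continue
            first = False
            if len(cells) == 1:
                token = cells[0]
                n_sep = token.count("-")
                if n_sep == 0:
                    raise RowParseError(
                        f"fusion token {token!r} has no '-' separator and no "
                        "two-column form",
                        line_no,
                    )
                if n_sep > 1:
                    raise AmbiguityError(
                        f"fusion token {token!r} contains multiple '-'; use the "
                        "TSV form (gene5<TAB>gene3) for symbols containing '-'",
                        line_no,
                    )
                gene5, gene3 = token.split("-")
            else:
                gene5, gene3 = cells[0], cells[1]
            sample = cells[2] if len(cells) > 2 and cells[2] not in _MISSING else None
            bp5 = cells[3] if len(cells) > 3 and cells[3] not in _MISSING else None
            bp3 = cells[4] if len(cells) > 4 and cells[4] not in _MISSING else None
            try:
                fusions.append(
                    FusionCandidate(
                        gene5=gene5,
                        gene3=gene3,
                        sample_id=sample,
                        breakpoint5=int(bp5) if bp5 is not None else None,
                        breakpoint3=int(bp3) if bp3 is not None else None,
                    )
                )
            except (ValidationError, ValueError) as exc:
                raise RowParseError(str(exc), line_no) from exc
    return fusions


def _dict_reader(stream: IO[str], required: tuple[str, ...], what: str):
    reader = csv.DictReader(stream, delimiter="\t")
    if reader.fieldnames is None:
        raise SchemaError(f"{what} table is empty (no header row)")
    fields = [f.strip().casefold() for f in reader.fieldnames]
    for col in required:
        if col not in fields:
            raise SchemaError(f"{what} table is missing required header {col!r}")
    for row in reader:
        yield {k.strip().casefold(): (v or "").strip() for k, v in row.items() if k}


def _split_list(value: str) -> list[str]:
    return [tok.strip() for tok in value.split(",") if tok.strip()]


def read_gene_models(source) -> dict[str, GeneModel]:
    """Read a headered gene-model TSV into a case-folded symbol lookup.

    Duplicate symbols (after case-folding) are an error: the gene model
    table is the coordinate authority and must be unambiguous.
    """
    genes: dict[str, GeneModel] = {}
    with _open_text(source) as stream:
        for row in _dict_reader(
            stream, ("symbol", "chrom", "start", "end", "strand"), "gene-model"
        ):
            gene = GeneModel(
                symbol=row["symbol"],
                chrom=row["chrom"],
                start=int(row["start"]),
                end=int(row["end"]),
                strand=row["strand"],
            )
            if gene.key in genes:
                raise ValidationError(
                    f"duplicate gene-model symbol {gene.symbol!r} (case-insensitive)"
                )
            genes[gene.key] = gene
    return genes


def read_census(source) -> dict[str, CensusRecord]:
    """Read a cancer-census TSV into a case-folded symbol lookup.

    On duplicate symbols the last record wins, with a logged warning.
    """
    census: dict[str, CensusRecord] = {}
    with _open_text(source) as stream:
        for row in _dict_reader(
            stream, ("symbol", "role", "tumor_types", "mutation_types"), "census"
        ):
            rec = CensusRecord(
                symbol=row["symbol"],
                role=row["role"],
                tumor_types=_split_list(row["tumor_types"]),
                mutation_types=_split_list(row["mutation_types"]),
            )
            if rec.key in census:
                logger.warning(
                    "duplicate census symbol %r: keeping the last record", rec.symbol
                )
            census[rec.key] = rec
    return census


def read_domains(source) -> dict[str, list[DomainRecord]]:
    """Read a protein-domain TSV into per-symbol ordered domain lists."""
    domains: dict[str, list[DomainRecord]] = {}
    with _open_text(source) as stream:
        for row in _dict_reader(
            stream,
            ("symbol", "domain_name", "start_aa", "end_aa", "source_id"),
            "domain",
        ):
            rec = DomainRecord(
                symbol=row["symbol"],
                domain_name=row["domain_name"],
                start_aa=int(row["start_aa"]),
                end_aa=int(row["end_aa"]),
                source_id=row["source_id"],
            )
            domains.setdefault(rec.symbol.casefold(), []).append(rec)
    return domains


def format_r(r) -> str:
    """Serialize a correlation value; not-computable becomes 'NA'."""
    if r is None:
        return "NA"
    return format(float(r), ".6g")


def write_driver_report(calls: Iterable, sink) -> None:
    """Write driver-triage verdicts as TSV, one row per fusion, input order.

    ``calls`` is any iterable of :class:`~fusiontriage.triage.DriverCall`.
    """
    if calls is None:
        raise ValidationError("calls must not be None")
    with _open_text(sink, "wt") as stream:
        stream.write("\t".join(REPORT_COLUMNS) + "\n")
        for call in calls:
            row = (
                call.fusion.fusion_id,
                call.fusion.sample_id or "",
                call.status,
                str(len(call.evidence.sv_hits)),
                ",".join(sorted(call.sv_classes)),
                str(len(call.evidence.cnv_hits)),
                call.cnv_direction_5,
                call.cnv_direction_3,
                format_r(call.correlation_r),
                call.role_5,
                call.role_3,
            )
            stream.write("\t".join(row) + "\n")


def read_driver_report(source) -> list[dict]:
    """Read a driver report back into typed row dictionaries."""
    rows: list[dict] = []
    with _open_text(source) as stream:
        for row in _dict_reader(stream, REPORT_COLUMNS, "driver report"):
            rows.append(
                {
                    "fusion_id": row["fusion_id"],
                    "sample_id": row["sample_id"] or None,
                    "status": row["status"],
                    "n_sv_hits": int(row["n_sv_hits"]),
                    "sv_classes": _split_list(row["sv_classes"]),
                    "n_cnv_hits": int(row["n_cnv_hits"]),
                    "cnv_direction_5": row["cnv_direction_5"],
                    "cnv_direction_3": row["cnv_direction_3"],
                    "correlation_r": (
                        None if row["correlation_r"] == "NA" else float(row["correlation_r"])
                    ),
                    "role_5": row["role_5"],
                    "role_3": row["role_3"],
                }
            )
    return rows


def write_cnv_segments(segments: Iterable[CNVSegment], sink) -> None:
    """Write segments as a 6-column TSV with header."""
    with _open_text(sink, "wt") as stream:
        stream.write("\t".join(CNV_COLUMNS) + "\n")
        for seg in segments:
            stream.write(
                "\t".join(
                    (
                        seg.sample_id,
                        seg.chrom,
                        str(seg.start),
                        str(seg.end),
                        seg.probe_field,
                        repr(seg.segmean),  # shortest exact representation
                    )
                )
                + "\n"
            )


def write_sv_calls(calls: Iterable[SVCall], sink) -> None:
    """Write calls as an 8-column TSV with header."""
    with _open_text(sink, "wt") as stream:
        stream.write("\t".join(SV_COLUMNS) + "\n")
        for c in calls:
            stream.write(
                "\t".join(
                    (
                        c.sample_id,
                        c.chrom1,
                        str(c.pos1),
                        c.strand1,
                        c.chrom2,
                        str(c.pos2),
                        c.strand2,
                        c.svclass,
                    )
                )
                + "\n"
            )


def write_fusions(fusions: Iterable[FusionCandidate], sink) -> None:
    """Write fusions in the 5-column TSV form."""
    with _open_text(sink, "wt") as stream:
        stream.write("gene5\tgene3\tsample_id\tbreakpoint5\tbreakpoint3\n")
        for f in fusions:
            stream.write(
                "\t".join(
                    (
                        f.gene5,
                        f.gene3,
                        f.sample_id or "",
                        str(f.breakpoint5) if f.breakpoint5 is not None else "",
                        str(f.breakpoint3) if f.breakpoint3 is not None else "",
                    )
                )
                + "\n"
            )
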