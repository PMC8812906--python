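"""Synthetic SV/CNV/fusion bundles with planted ground truth.

The generator emulates the statistical structure the triage method
assumes: forming a real fusion leaves both a rearrangement footprint (an
SV breakend inside a partner gene) and a dosage footprint (a CNV segment
with a clear log-ratio step over a partner) in the same sample, while
incidental fusion calls co-occur with neither.

Construction guarantees, at zero evidence dropout:

* every planted **Driver** has ≥1 SV breakend inside a partner gene body
  and ≥1 CNV segment overlapping a partner with |segmean| ≥ 0.4, both in
  the fusion's own sample;
* every planted **Passenger** has *no* evidence of either kind within the
  padding distance of either partner — background noise is rejection-
  sampled away from all partner loci. Recovery by the default triage
  config is therefore exact, not probabilistic.

Partner genes of different fusions are kept far enough apart that one
fusion's planted evidence can never leak into another's search window,
which also makes the corruption operations surgical: dropping one
driver's planted rows flips exactly that driver.

The optional *hard negatives* mode plants SV-only and CNV-only near
misses on some passengers to exercise the evidence conjunction; they
remain passengers because one evidence type alone never suffices.

Everything is driven by one :class:`numpy.random.Generator` seeded from
``SimConfig.seed``: identical configs produce byte-identical bundles.
"""

from __future__ import annotations

import copy
import os
from dataclasses import dataclass, field, replace
from math import copysign
from typing import Literal

import numpy as np

from . import io as ftio
from .errors import ValidationError
from .records import (
    CensusRecord,
    CNVSegment,
    DomainRecord,
    FusionCandidate,
    GeneModel,
    SVCall,
)
from .triage import DriverCall, TriageConfig, classify_all

BUNDLE_FILES = (
    "cnv.tsv",
    "sv.tsv",
    "fusions.tsv",
    "genes.tsv",
    "census.tsv",
    "domains.tsv",
    "truth.tsv",
)

_ROLES_CYCLE = ("oncogene", "TSG", "fusion", "oncogene+TSG")
_TUMORS = ("NSCLC", "breast", "AML", "CRC")
_MUTATIONS = ("translocation", "amplification", "missense", "frameshift")


@dataclass
class SimConfig:
    """Study conditions for one synthetic bundle."""

    seed: int = 0
    n_chromosomes: int = 5
    chrom_length_bp: int = 10_000_000
    n_genes: int = 200
    gene_min_bp: int = 5_000
    gene_max_bp: int = 200_000
    n_fusions: int = 50
    driver_fraction: float = 0.4
    sv_noise_count: int = 100
    cnv_noise_segments: int = 50
    cnv_noise_sd: float = 0.05
    driver_cnv_min_abs: float = 0.4
    driver_cnv_max_abs: float = 1.2
    evidence_dropout: float = 0.0
    hard_negatives: bool = False
    n_samples: int = 4
    #: clearance the generator keeps evidence-free around passenger partners
    padding_bp: int = 50_000
    #: planted CNV segments may extend at most this far beyond the gene body
    plant_flank_max_bp: int = 20_000

    def __post_init__(self) -> None:
        if not (0.0 <= self.driver_fraction <= 1.0):
            raise ValidationError("driver_fraction must be in [0, 1]")
        if not (0.0 <= self.evidence_dropout <= 1.0):
            raise ValidationError("evidence_dropout must be in [0, 1]")
        if self.n_genes < 2 * self.n_fusions:
            raise ValidationError(
                f"need at least {2 * self.n_fusions} genes for {self.n_fusions} fusions"
            )


@dataclass
class TruthRecord:
    """Planted label and evidence row ids for one simulated fusion."""

    fusion_id: str
    planted_label: str  # 'Driver' or 'Passenger'
    planted_sv_ids: list[str] = field(default_factory=list)
    planted_cnv_ids: list[str] = field(default_factory=list)


@dataclass
class SimBundle:
    """An in-memory input bundle plus its ground truth."""

    config: SimConfig
    cnv: list[CNVSegment]
    cnv_ids: list[str]
    sv: list[SVCall]
    sv_ids: list[str]
    fusions: list[FusionCandidate]
    genes: dict[str, GeneModel]
    census: dict[str, CensusRecord]
    domains: dict[str, list[DomainRecord]]
    truth: list[TruthRecord]

    def classify(self, cfg: TriageConfig | None = None, **kwargs) -> list[DriverCall]:
        """Run the triage on this bundle's inputs."""
        return classify_all(
            self.fusions, self.sv, self.cnv, self.genes, self.census,
            cfg=cfg, **kwargs,
        )


def _place_genes(cfg: SimConfig, rng: np.random.Generator) -> list[GeneModel]:
    placed: dict[str, list[tuple[int, int]]] = {
        str(c + 1): [] for c in range(cfg.n_chromosomes)
    }
    genes: list[GeneModel] = []
    for i in range(cfg.n_genes):
        chrom = str((i % cfg.n_chromosomes) + 1)
        for _attempt in range(500):
            width = int(rng.integers(cfg.gene_min_bp, cfg.gene_max_bp + 1))
            start = int(rng.integers(1, cfg.chrom_length_bp - width + 1))
            end = start + width - 1
            if all(e < start or end < s for s, e in placed[chrom]):
                placed[chrom].append((start, end))
                strand = "+" if rng.random() < 0.5 else "-"
                genes.append(
                    GeneModel(
                        symbol=f"G{i + 1:04d}", chrom=chrom, start=start, end=end,
                        strand=strand,
                    )
                )
                break
        else:
            raise ValidationError(
                "infeasible gene layout: could not place non-overlapping genes; "
                "increase chrom_length_bp or reduce n_genes/gene widths"
            )
    return genes


def _select_partners(cfg: SimConfig, genes: list[GeneModel]) -> list[GeneModel]:
    """Pick 2*n_fusions genes pairwise separated by more than the reach of
    planted evidence plus the padding window, so evidence cannot leak
    between fusions."""
    clearance = cfg.padding_bp + cfg.plant_flank_max_bp + 5_000
    selected: list[GeneModel] = []
    last_end: dict[str, int] = {}
    for gene in sorted(genes, key=lambda g: (g.chrom, g.start)):
        if gene.chrom in last_end and gene.start - last_end[gene.chrom] <= clearance:
            continue
        selected.append(gene)
        last_end[gene.chrom] = gene.end
        if len(selected) == 2 * cfg.n_fusions:
            return selected
    raise ValidationError(
        "infeasible layout: not enough well-separated genes for "
        f"{cfg.n_fusions} fusions; increase chrom_length_bp or n_genes"
    )


class _Exclusions:
    """Padded windows around all partner genes; noise must stay outside."""

    def __init__(self, partners: list[GeneModel], padding_bp: int):
        self.zones: dict[str, list[tuple[int, int]]] = {}
        for g in partners:
            self.zones.setdefault(g.chrom, []).append(
                (max(1, g.start - padding_bp), g.end + padding_bp)
            )

    def point_ok(self, chrom: str, pos: int) -> bool:
        return all(pos < lo or pos > hi for lo, hi in self.zones.get(chrom, ()))

    def interval_ok(self, chrom: str, start: int, end: int) -> bool:
        return all(end < lo or hi < start for lo, hi in self.zones.get(chrom, ()))


def _free_point(
    cfg: SimConfig, rng: np.random.Generator, excl: _Exclusions,
    chrom: str | None = None,
) -> tuple[str, int]:
    for _ in range(10_000):
        c = chrom or str(int(rng.integers(1, cfg.n_chromosomes + 1)))
        pos = int(rng.integers(1, cfg.chrom_length_bp + 1))
        if excl.point_ok(c, pos):
            return c, pos
    raise ValidationError("could not place background breakend outside partner windows")


def _strand(rng: np.random.Generator) -> str:
    return "+" if rng.random() < 0.5 else "-"


def generate_bundle(cfg: SimConfig, out_dir: str | None = None) -> SimBundle:
    """Generate a complete input bundle; optionally write it to ``out_dir``."""
    rng = np.random.default_rng(cfg.seed)

    genes = _place_genes(cfg, rng)
    partners = _select_partners(cfg, genes)
    order = rng.permutation(len(partners))
    excl = _Exclusions(partners, cfg.padding_bp)

    n_driver = round(cfg.n_fusions * cfg.driver_fraction)
    label_order = rng.permutation(cfg.n_fusions)
    labels = ["Passenger"] * cfg.n_fusions
    for idx in label_order[:n_driver]:
        labels[int(idx)] = "Driver"

    fusions: list[FusionCandidate] = []
    truth: list[TruthRecord] = []
    sv: list[SVCall] = []
    sv_ids: list[str] = []
    cnv: list[CNVSegment] = []
    cnv_ids: list[str] = []

    def _add_sv(call: SVCall) -> str:
        sv_id = f"sv{len(sv):04d}"
        sv.append(call)
        sv_ids.append(sv_id)
        return sv_id

    def _add_cnv(seg: CNVSegment) -> str:
        cnv_id = f"cnv{len(cnv):04d}"
        cnv.append(seg)
        cnv_ids.append(cnv_id)
        return cnv_id

    def _plant_sv(gene: GeneModel, sample: str) -> str:
        be1 = int(rng.integers(gene.start, gene.end + 1))
        if rng.random() < 0.5:  # interchromosomal partner breakend
            others = [
                str(c + 1) for c in range(cfg.n_chromosomes) if str(c + 1) != gene.chrom
            ]
            c2 = others[int(rng.integers(0, len(others)))]
            _, p2 = _free_point(cfg, rng, excl, chrom=c2)
            svclass = "translocation"
        else:
            c2, p2 = _free_point(cfg, rng, excl, chrom=gene.chrom)
            svclass = ("duplication", "deletion", "inversion")[int(rng.integers(0, 3))]
        return _add_sv(
            SVCall(sample, gene.chrom, be1, _strand(rng), c2, p2, _strand(rng), svclass)
        )

    def _plant_cnv(gene: GeneModel, sample: str) -> str:
        u1 = int(rng.integers(0, cfg.plant_flank_max_bp + 1))
        u2 = int(rng.integers(0, cfg.plant_flank_max_bp + 1))
        mag = float(rng.uniform(cfg.driver_cnv_min_abs, cfg.driver_cnv_max_abs))
        sign = 1.0 if rng.random() < 0.5 else -1.0
        return _add_cnv(
            CNVSegment(
                sample, gene.chrom, max(1, gene.start - u1), gene.end + u2,
                str(int(rng.integers(10, 1000))), sign * mag,
            )
        )

    hard_negative_parity = 0
    for i in range(cfg.n_fusions):
        g5, g3 = partners[int(order[2 * i])], partners[int(order[2 * i + 1])]
        sample = f"S{int(rng.integers(1, cfg.n_samples + 1)):02d}"
        fusion = FusionCandidate(gene5=g5.symbol, gene3=g3.symbol, sample_id=sample)
        fusions.append(fusion)
        rec = TruthRecord(fusion_id=fusion.fusion_id, planted_label=labels[i])

        if labels[i] == "Driver":
            drop_sv = drop_cnv = False
            if cfg.evidence_dropout > 0 and rng.random() < cfg.evidence_dropout:
                drop_sv = rng.random() < 0.5
                drop_cnv = not drop_sv
            sv_gene = g5 if rng.random() < 0.5 else g3
            cnv_gene = g5 if rng.random() < 0.5 else g3
            if not drop_sv:
                rec.planted_sv_ids.append(_plant_sv(sv_gene, sample))
            if not drop_cnv:
                rec.planted_cnv_ids.append(_plant_cnv(cnv_gene, sample))
        elif cfg.hard_negatives:
            # alternate SV-only / CNV-only near-misses on passengers
            gene = g5 if rng.random() < 0.5 else g3
            if hard_negative_parity == 0:
                rec.planted_sv_ids.append(_plant_sv(gene, sample))
            else:
                rec.planted_cnv_ids.append(_plant_cnv(gene, sample))
            hard_negative_parity ^= 1
        truth.append(rec)

    for _ in range(cfg.sv_noise_count):
        c1, p1 = _free_point(cfg, rng, excl)
        if rng.random() < 0.5:
            c2, p2 = _free_point(cfg, rng, excl)
            while c2 == c1:
                c2, p2 = _free_point(cfg, rng, excl)
            svclass = "translocation"
        else:
            c2, p2 = _free_point(cfg, rng, excl, chrom=c1)
            svclass = ("duplication", "deletion", "inversion", "insertion")[
                int(rng.integers(0, 4))
            ]
        sample = f"S{int(rng.integers(1, cfg.n_samples + 1)):02d}"
        _add_sv(SVCall(sample, c1, p1, _strand(rng), c2, p2, _strand(rng), svclass))

    for _ in range(cfg.cnv_noise_segments):
        for _attempt in range(10_000):
            chrom = str(int(rng.integers(1, cfg.n_chromosomes + 1)))
            length = int(rng.integers(20_000, 500_001))
            start = int(rng.integers(1, cfg.chrom_length_bp - length + 1))
            if excl.interval_ok(chrom, start, start + length - 1):
                break
        else:
            raise ValidationError("could not place background CNV segment")
        sample = f"S{int(rng.integers(1, cfg.n_samples + 1)):02d}"
        segmean = float(rng.normal(0.0, cfg.cnv_noise_sd))
        if segmean == 0.0:  # degenerate draw; nudge off exact zero
            segmean = 1e-6
        _add_cnv(
            CNVSegment(
                sample, chrom, start, start + length - 1,
                str(int(rng.integers(10, 1000))), segmean,
            )
        )

    # census roles for a handful of driver partners, to exercise annotation
    census: dict[str, CensusRecord] = {}
    driver_partner_syms = []
    for i, rec in enumerate(truth):
        if rec.planted_label == "Driver":
            driver_partner_syms.extend([fusions[i].gene5, fusions[i].gene3])
    for j, symbol in enumerate(driver_partner_syms[:8]):
        role = _ROLES_CYCLE[j % len(_ROLES_CYCLE)]
        record = CensusRecord(
            symbol=symbol,
            role=role,
            tumor_types=[_TUMORS[j % len(_TUMORS)]],
            mutation_types=[_MUTATIONS[j % len(_MUTATIONS)]],
        )
        census[record.key] = record

    # protein domains for every fusion partner gene
    domains: dict[str, list[DomainRecord]] = {}
    for k, gene in enumerate(partners):
        protein_len = int(rng.integers(300, 1201))
        n_dom = int(rng.integers(1, 5))
        cursor = 1
        track: list[DomainRecord] = []
        for d in range(n_dom):
            remaining = protein_len - cursor
            if remaining < 30:
                break
            gap = int(rng.integers(0, max(1, remaining // (n_dom * 2)) + 1))
            width = int(rng.integers(25, max(26, remaining // n_dom) + 1))
            start_aa = cursor + gap
            end_aa = min(start_aa + width - 1, protein_len)
            if start_aa > end_aa:
                break
            track.append(
                DomainRecord(
                    symbol=gene.symbol,
                    domain_name=f"DOM{d + 1}",
                    start_aa=start_aa,
                    end_aa=end_aa,
                    source_id=f"SYN{k:04d}.{d + 1}",
                )
            )
            cursor = end_aa + 1
        if track:
            domains[gene.key] = track

    bundle = SimBundle(
        config=cfg,
        cnv=cnv,
        cnv_ids=cnv_ids,
        sv=sv,
        sv_ids=sv_ids,
        fusions=fusions,
        genes={g.key: g for g in genes},
        census=census,
        domains=domains,
        truth=truth,
    )
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def corrupt_bundle(
    bundle: SimBundle,
    mode: Literal["drop_sv", "drop_cnv", "subthreshold_cnv"],
    targets: list[str],
) -> SimBundle:
    """Surgically remove or weaken planted evidence for chosen drivers.

    ``targets`` must all be planted Drivers. ``drop_sv``/``drop_cnv``
    delete the planted rows; ``subthreshold_cnv`` rescales the planted
    segmean magnitude to 0.1 (keeping its sign), below the default 0.2
    evidence threshold but above a permissive 0.05 one.
    """
    if mode not in ("drop_sv", "drop_cnv", "subthreshold_cnv"):
        raise ValidationError(f"unknown corruption mode {mode!r}")
    truth_by_id = {t.fusion_id: t for t in bundle.truth}
    for target in targets:
        rec = truth_by_id.get(target)
        if rec is None or rec.planted_label != "Driver":
            raise ValidationError(
                f"corruption target {target!r} is not a planted Driver"
            )

    drop_sv_ids: set[str] = set()
    drop_cnv_ids: set[str] = set()
    scale_cnv_ids: set[str] = set()
    for target in targets:
        rec = truth_by_id[target]
        if mode == "drop_sv":
            drop_sv_ids.update(rec.planted_sv_ids)
        elif mode == "drop_cnv":
            drop_cnv_ids.update(rec.planted_cnv_ids)
        else:
            scale_cnv_ids.update(rec.planted_cnv_ids)

    new_sv, new_sv_ids = [], []
    for call, sid in zip(bundle.sv, bundle.sv_ids):
        if sid not in drop_sv_ids:
            new_sv.append(copy.copy(call))
            new_sv_ids.append(sid)
    new_cnv, new_cnv_ids = [], []
    for seg, cid in zip(bundle.cnv, bundle.cnv_ids):
        if cid in drop_cnv_ids:
            continue
        if cid in scale_cnv_ids:
            seg = replace(seg, segmean=copysign(0.1, seg.segmean))
        else:
            seg = copy.copy(seg)
        new_cnv.append(seg)
        new_cnv_ids.append(cid)

    return SimBundle(
        config=bundle.config,
        cnv=new_cnv,
        cnv_ids=new_cnv_ids,
        sv=new_sv,
        sv_ids=new_sv_ids,
        fusions=list(bundle.fusions),
        genes=dict(bundle.genes),
        census=dict(bundle.census),
        domains=dict(bundle.domains),
        truth=[copy.deepcopy(t) for t in bundle.truth],
    )


def write_bundle(bundle: SimBundle, out_dir: str) -> None:
    """Write the bundle as the seven TSV files listed in BUNDLE_FILES."""
    os.makedirs(out_dir, exist_ok=True)
    ftio.write_cnv_segments(bundle.cnv, os.path.join(out_dir, "cnv.tsv"))
    ftio.write_sv_calls(bundle.sv, os.path.join(out_dir, "sv.tsv"))
    ftio.write_fusions(bundle.fusions, os.path.join(out_dir, "fusions.tsv"))
    with open(os.path.join(out_dir, "genes.tsv"), "w") as fh:
        fh.write("symbol\tchrom\tstart\tend\tstrand\n")
        for g in sorted(bundle.genes.values(), key=lambda g: g.symbol):
            fh.write(f"{g.symbol}\t{g.chrom}\t{g.start}\t{g.end}\t{g.strand}\n")
    with open(os.path.join(out_dir, "census.tsv"), "w") as fh:
        fh.write("symbol\trole\ttumor_types\tmutation_types\n")
        for rec in sorted(bundle.census.values(), key=lambda r: r.symbol):
            fh.write(
                f"{rec.symbol}\t{rec.role}\t{','.join(rec.tumor_types)}\t"
                f"{','.join(rec.mutation_types)}\n"
            )
    with open(os.path.join(out_dir, "domains.tsv"), "w") as fh:
        fh.write("symbol\tdomain_name\tstart_aa\tend_aa\tsource_id\n")
        for key in sorted(bundle.domains):
            for d in bundle.domains[key]:
                fh.write(
                    f"{d.symbol}\t{d.domain_name}\t{d.start_aa}\t{d.end_aa}\t"
                    f"{d.source_id}\n"
                )
    with open(os.path.join(out_dir, "truth.tsv"), "w") as fh:
        fh.write("fusion_id\tplanted_label\tplanted_sv_ids\tplanted_cnv_ids\n")
        for t in bundle.truth:
            fh.write(
                f"{t.fusion_id}\t{t.planted_label}\t"
                f"{','.join(t.planted_sv_ids)}\t{','.join(t.planted_cnv_ids)}\n"
            )


def read_truth(source) -> list[TruthRecord]:
    """Read a truth.tsv back into TruthRecord rows."""
    records: list[TruthRecord] = []
    with ftio._open_text(source) as stream:
        for row in ftio._dict_reader(
            stream,
            ("fusion_id", "planted_label", "planted_sv_ids", "planted_cnv_ids"),
            "truth",
        ):
            records.append(
                TruthRecord(
                    fusion_id=row["fusion_id"],
                    planted_label=row["planted_label"],
                    planted_sv_ids=ftio._split_list(row["planted_sv_ids"]),
                    planted_cnv_ids=ftio._split_list(row["planted_cnv_ids"]),
                )
            )
    return records
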