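from __future__ import annotations

import numpy as np
import pytest

from fusiontriage import SimConfig, generate_bundle
from fusiontriage.records import CNVSegment, FusionCandidate, GeneModel, SVCall


@pytest.fixture(scope="session")
def bundle7():
    """The default study-condition bundle: 50 fusions, 40% drivers, no dropout."""
    return generate_bundle(SimConfig(seed=7))


@pytest.fixture(scope="session")
def calls7(bundle7):
    return bundle7.classify()


@pytest.fixture()
def tiny_genes():
    genes = [
        GeneModel("ALPHA", "1", 1_000_000, 1_050_000, "+"),
        GeneModel("BETA", "2", 2_000_000, 2_040_000, "-"),
        GeneModel("GAMMA", "3", 500_000, 560_000, "+"),
    ]
    return {g.key: g for g in genes}


def random_instance(seed: int):
    """A small random triage problem for oracle-equivalence checks.

    Genes may overlap, fusions may reference missing symbols or lack a
    sample id, and SV/CNV records are scattered both near and far from
    gene loci — the messy cases the indexed path must match the naive
    scan on.
    """
    rng = np.random.default_rng(seed)
    chroms = [str(c) for c in range(1, 4)]
    genome = 2_000_000
    genes = {}
    for i in range(12):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        start = int(rng.integers(1, genome - 100_000))
        end = start + int(rng.integers(5_000, 100_000))
        g = GeneModel(f"R{i:03d}", chrom, start, end, "+")
        genes[g.key] = g
    symbols = [g.symbol for g in genes.values()] + ["MISSING1", "MISSING2"]
    samples = ["A", "B", None]
    fusions = []
    for _ in range(15):
        g5, g3 = rng.choice(symbols, size=2, replace=False)
        fusions.append(
            FusionCandidate(
                gene5=str(g5),
                gene3=str(g3),
                sample_id=samples[int(rng.integers(0, 3))],
            )
        )
    classes = ["duplication", "deletion", "inversion", "insertion", "translocation"]
    sv = []
    for _ in range(40):
        c1 = chroms[int(rng.integers(0, 3))]
        c2 = chroms[int(rng.integers(0, 3))]
        svclass = "translocation" if c1 != c2 else classes[int(rng.integers(0, 4))]
        sv.append(
            SVCall(
                sample_id=["A", "B"][int(rng.integers(0, 2))],
                chrom1=c1,
                pos1=int(rng.integers(1, genome)),
                strand1="+" if rng.random() < 0.5 else "-",
                chrom2=c2,
                pos2=int(rng.integers(1, genome)),
                strand2="+" if rng.random() < 0.5 else "-",
                svclass=svclass,
            )
        )
    cnv = []
    for _ in range(30):
        chrom = chroms[int(rng.integers(0, 3))]
        start = int(rng.integers(1, genome - 200_000))
        cnv.append(
            CNVSegment(
                sample_id=["A", "B"][int(rng.integers(0, 2))],
                chrom=chrom,
                start=start,
                end=start + int(rng.integers(1_000, 200_000)),
                probe_field=str(int(rng.integers(1, 500))),
                segmean=float(rng.normal(0, 0.4)),
            )
        )
    return fusions, sv, cnv, genes
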