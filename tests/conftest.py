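import json
import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from crossbind.intervals import GenomicInterval, GeneModel, Peak
from crossbind.pipeline import make_fixture, run_full_analysis
from crossbind.simulate import SimulationConfig


def random_gene(rng, chrom: str, start: int, gene_id: str) -> GeneModel:
    """Small random gene with 2-4 exons for oracle comparisons."""
    n_exons = int(rng.integers(2, 5))
    cursor = start
    exons = []
    strand = "+" if rng.random() < 0.5 else "-"
    for j in range(n_exons):
        elen = int(rng.integers(80, 300))
        exons.append(GenomicInterval(chrom, cursor, cursor + elen, strand))
        cursor += elen
        if j < n_exons - 1:
            cursor += int(rng.integers(200, 1500))
    body = GenomicInterval(chrom, start, cursor, strand)
    return GeneModel(gene_id=gene_id, interval=body, strand=strand, exons=tuple(exons))


def random_annotation(rng, n_genes: int = 8, chrom: str = "chr1") -> list[GeneModel]:
    genes = []
    pos = int(rng.integers(0, 3000))
    for i in range(n_genes):
        g = random_gene(rng, chrom, pos, f"g{i:02d}")
        genes.append(g)
        pos = g.interval.end + int(rng.integers(500, 8000))
    return genes


def make_peak(chrom, start, end, pid="p", tissue="", summit=None, score=0.0):
    return Peak(
        interval=GenomicInterval(chrom, start, end),
        id=pid,
        tissue=tissue,
        score=score,
        summit=summit,
    )


@pytest.fixture(scope="session")
def default_fixture(tmp_path_factory):
    """The default synthetic study (2000 genes), run end-to-end once.

    Returns (run config, full report, truth manifest). Shared by the
    parameter-recovery and contrast tests, which only read from it.
    """
    root = tmp_path_factory.mktemp("default_fixture")
    sim_cfg = SimulationConfig(seed=11)
    cfg = make_fixture(sim_cfg, root)
    report = run_full_analysis(cfg)
    manifest = json.loads((root / "input" / "manifest.json").read_text())
    return cfg, report, manifest


@pytest.fixture(scope="session")
def small_fixture(tmp_path_factory):
    """A 150-gene fixture for fast end-to-end checks."""
    root = tmp_path_factory.mktemp("small_fixture")
    sim_cfg = SimulationConfig(
        seed=3, n_genes=150, n_chromosomes=2, chromosome_length=3_400_000
    )
    cfg = make_fixture(sim_cfg, root)
    report = run_full_analysis(cfg)
    manifest = json.loads((root / "input" / "manifest.json").read_text())
    return cfg, report, manifest
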