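import numpy as np
import pandas as pd
import pytest

from panpos.io import ChromosomeDef
from panpos.simulate import SyntheticConfig, simulate_pangenome


@pytest.fixture
def gff_text() -> str:
    """Five features on two chromosomes: 3 CDS (one wrapping), 2 tRNA."""
    return (
        "##gff-version 3\n"
        "##sequence-region chrA 1 10000\n"
        "##sequence-region chrB 1 5000\n"
        "chrA\tsrc\tCDS\t1\t300\t.\t+\t0\tID=gA1;cluster=c1\n"
        "chrA\tsrc\ttRNA\t400\t470\t.\t+\t0\tID=tA1\n"
        "chrA\tsrc\tCDS\t9901\t150\t.\t-\t0\tID=gA2;cluster=c2\n"
        "chrB\tsrc\tCDS\t2001\t2600\t.\t+\t0\tID=gB1;cluster=c1\n"
        "chrB\tsrc\ttRNA\t100\t170\t.\t-\t0\tID=tB1\n"
    )


@pytest.fixture
def gff_file(tmp_path, gff_text):
    p = tmp_path / "toy.gff3"
    p.write_text(gff_text)
    return p


@pytest.fixture
def matrix_file(tmp_path):
    """2 clusters x 3 genomes, clusters as rows, with a paralog cell."""
    p = tmp_path / "matrix.tsv"
    p.write_text("\tgenA\tgenB\tgenC\nc1\t1\t1\t1\nc2\t2\t0\t1\n")
    return p


@pytest.fixture
def toy_loci() -> pd.DataFrame:
    """10 hand-placed genes on one genome/chromosome with known halves."""
    L = 1000
    rows = []
    # (gene, category, midpoint) on a circle with ori at 0
    layout = [
        ("g1", "core", 10), ("g2", "core", 100), ("g3", "core", 900),
        ("g4", "softcore", 200), ("g5", "softcore", 800),
        ("g6", "shell", 400), ("g7", "shell", 500), ("g8", "shell", 600),
        ("g9", "cloud", 300), ("g10", "cloud", 700),
    ]
    for gid, cat, mid in layout:
        rows.append(
            dict(gene_id=gid, genome_id="G", chrom_id="chr1", cluster_id=gid,
                 category=cat, start_bp=(mid - 10) % L, end_bp=(mid + 10) % L,
                 strand="+")
        )
    return pd.DataFrame(rows)


@pytest.fixture
def chrom_defs():
    return [ChromosomeDef("chr1", 1000, ori_bp=0)]


@pytest.fixture(scope="session")
def small_dataset():
    """A small biased synthetic dataset shared by read-only tests."""
    cfg = SyntheticConfig(seed=42, n_genomes=6, n_clusters=1200,
                          occupancy_mix=(0.13, 0.15, 0.22, 0.50))
    return simulate_pangenome(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
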