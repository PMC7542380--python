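"""Synthetic pangenomes with planted positional bias and gene-dosage gradients.

The generator emulates the statistical structure the analysis assumes, so
every pipeline stage is testable without downloads and parameter recovery
is quantifiable:

* **U-shaped occupancy** — cluster occupancies drawn from a four-component
  mixture (core at N; softcore uniform on ``[softcore_min, N-1]``; shell
  uniform on ``[cloud_max+1, softcore_min-1]``; cloud uniform on
  ``[1, cloud_max]``), with mixture weights defaulting to the observed
  pangenome proportions (core-heavy at both tails of occupancy).
* **Planted positional bias** — on Chr 1 only (Chr 2 stays uniform), a
  gene's relative distance to *ori* ``u`` is Beta(1, 1+b) for core/softcore
  (mass near *ori*) and Beta(1+b, 1) for shell/cloud (mass near *ter*);
  ``b = 0`` recovers uniform placement.  Beta keeps the bias one-parameter
  with a closed-form mean ``E[u] = 1/(2+b)`` for Beta(1, 1+b).
* **Gene dosage** — expected expression decays with distance from *ori1*
  as ``2**(k * (1 - u))``, a minimal monotone copy-number law: ``k`` is the
  dosage exponent (strong for fast growth, 0 for slow growth).  Counts are
  Poisson around the expectation after multiplicative lognormal noise
  ``exp(eps)``, ``eps ~ N(0, sigma^2)``.

Everything is a deterministic function of the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .classify import PangenomeMatrix, softcore_threshold
from .io import ChromosomeDef, write_gff, write_ori_table, frame_to_genes

__all__ = ["SyntheticConfig", "SyntheticDataset", "simulate_pangenome",
           "simulate_counts", "truth_report"]

_CATS = ("core", "softcore", "shell", "cloud")


@dataclass
class SyntheticConfig:
    """All generator parameters; the seed fully determines the output."""

    seed: int = 0
    n_genomes: int = 12
    chr1_length_bp: int = 3_200_000
    chr2_length_bp: int = 1_800_000
    n_clusters: int = 6000
    #: mixture weights (core, softcore, shell, cloud) over clusters
    occupancy_mix: tuple[float, float, float, float] = (0.012, 0.018, 0.23, 0.74)
    softcore_fraction: float = 0.95
    cloud_max: int = 2
    #: Beta bias parameter b; 0 = uniform positions
    bias_strength: float = 3.0
    chr1_bias_on: bool = True
    #: dosage exponent k at fast growth; slow growth uses k = 0
    dosage_exponent_k: float = 1.5
    chr2_dosage_flat: bool = True
    category_baseline: dict = field(
        default_factory=lambda: {"core": 4.0, "softcore": 3.0, "shell": 1.0, "cloud": 0.5}
    )
    #: sd of the multiplicative lognormal expression noise (natural log)
    noise_sd_log: float = 0.3
    library_size: int = 5_000_000
    #: lognormal gene length law, parameterised by its mean and sd in bp
    gene_length_mean_bp: float = 900.0
    gene_length_sd_bp: float = 600.0
    #: probability a present gene has a second (paralogous) copy
    paralog_prob: float = 0.02
    #: fraction of clusters on Chr 1 (None = proportional to length)
    chr1_fraction: float | None = None
    #: optional residual per-category dosage-like gradients at slow growth,
    #: mimicking position bias of non-core expression that persists without
    #: multifork replication (mechanism unmodelled; not a literature value)
    slow_residual_k: dict | None = None

    def __post_init__(self) -> None:
        if abs(sum(self.occupancy_mix) - 1.0) > 1e-9:
            raise ValueError("occupancy_mix must sum to 1")
        if min(self.occupancy_mix) < 0:
            raise ValueError("occupancy_mix must be non-negative")
        if self.chr1_length_bp <= 0 or self.chr2_length_bp <= 0:
            raise ValueError("chromosome lengths must be positive")
        if self.bias_strength < 0 or self.dosage_exponent_k < 0:
            raise ValueError("bias_strength and dosage_exponent_k must be >= 0")


@dataclass
class SyntheticDataset:
    """Generated genomes, matrix and the per-gene truth table."""

    config: SyntheticConfig
    chromosomes: list[ChromosomeDef]
    genes: pd.DataFrame      # gene_id genome_id chrom_id start_bp end_bp strand cluster_id category
    matrix: PangenomeMatrix
    truth: pd.DataFrame      # gene_id genome_id chrom_id category u half expected_dosage_fast

    @property
    def genome_ids(self) -> list[str]:
        return self.matrix.genome_ids

    def genes_of(self, genome_id: str) -> pd.DataFrame:
        return self.genes[self.genes["genome_id"] == genome_id].reset_index(drop=True)

    def write(self, out_dir: str | Path) -> None:
        """Emit GFF3 per genome, ori CSV, matrix TSV and truth TSV."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for gid in self.genome_ids:
            write_gff(frame_to_genes(self.genes_of(gid)), self.chromosomes,
                      out / f"{gid}.gff3")
        write_ori_table(self.chromosomes, out / "ori.csv")
        self.matrix.to_tsv(out / "matrix.tsv")
        truth_report(self, out / "truth.tsv")


def _occupancies(rng, cat_idx, cfg: SyntheticConfig) -> np.ndarray:
    n = cfg.n_genomes
    sc_min = softcore_threshold(n, cfg.softcore_fraction)
    if cfg.occupancy_mix[1] > 0 and sc_min > n - 1:
        raise ValueError("infeasible softcore occupancy range: softcore_min > N-1")
    if cfg.occupancy_mix[2] > 0 and cfg.cloud_max + 1 > sc_min - 1:
        raise ValueError("infeasible shell occupancy range: softcore_min <= cloud_max + 2")
    occ = np.empty(len(cat_idx), dtype=np.int64)
    occ[cat_idx == 0] = n
    for code, lo, hi in ((1, sc_min, n - 1), (2, cfg.cloud_max + 1, sc_min - 1),
                         (3, 1, cfg.cloud_max)):
        m = cat_idx == code
        if m.any():
            occ[m] = rng.integers(lo, hi + 1, size=m.sum())
    return occ


def simulate_pangenome(config: SyntheticConfig) -> SyntheticDataset:
    """Draw a full synthetic pangenome: matrix, coordinates, truth table."""
    cfg = config
    rng = np.random.default_rng([cfg.seed % (2**31), 11])
    C, N = cfg.n_clusters, cfg.n_genomes
    genome_ids = [f"g{i + 1:03d}" for i in range(N)]
    cluster_ids = np.array([f"c{i + 1:06d}" for i in range(C)])
    chr1 = ChromosomeDef("chr1", cfg.chr1_length_bp, ori_bp=cfg.chr1_length_bp // 10)
    chr2 = ChromosomeDef("chr2", cfg.chr2_length_bp, ori_bp=cfg.chr2_length_bp // 10)

    cat_idx = rng.choice(4, size=C, p=list(cfg.occupancy_mix))
    occ = _occupancies(rng, cat_idx, cfg)
    p1 = (cfg.chr1_fraction if cfg.chr1_fraction is not None
          else cfg.chr1_length_bp / (cfg.chr1_length_bp + cfg.chr2_length_bp))
    on_chr1 = rng.random(C) < p1

    # which genomes encode each cluster: the occ lowest ranks of a random matrix
    rank = rng.random((C, N)).argsort(axis=1).argsort(axis=1)
    present = rank < occ[:, None]
    ci, gi = np.nonzero(present)  # cluster index, genome index per gene

    n_genes = len(ci)
    cat_g = cat_idx[ci]
    chr1_g = on_chr1[ci]
    L = np.where(chr1_g, cfg.chr1_length_bp, cfg.chr2_length_bp).astype(np.int64)
    ori = np.where(chr1_g, chr1.ori_bp, chr2.ori_bp).astype(np.int64)

    # planted position law: Beta(1,1+b) toward ori for core/softcore,
    # Beta(1+b,1) toward ter for shell/cloud, uniform on chr2 or when b=0
    a = np.ones(n_genes)
    b = np.ones(n_genes)
    if cfg.chr1_bias_on and cfg.bias_strength > 0:
        ori_biased = chr1_g & (cat_g <= 1)
        ter_biased = chr1_g & (cat_g >= 2)
        b[ori_biased] = 1.0 + cfg.bias_strength
        a[ter_biased] = 1.0 + cfg.bias_strength
    u = rng.beta(a, b)
    side = np.where(rng.random(n_genes) < 0.5, 1, -1)

    sigma2 = np.log1p((cfg.gene_length_sd_bp / cfg.gene_length_mean_bp) ** 2)
    mu = np.log(cfg.gene_length_mean_bp) - sigma2 / 2
    length = np.clip(rng.lognormal(mu, np.sqrt(sigma2), n_genes).astype(np.int64),
                     90, L // 4)

    dist = np.rint(u * (L / 2.0)).astype(np.int64)
    pos = (ori + side * dist) % L
    start = (pos - length // 2) % L
    end = (start + length) % L

    # paralogs: extra copy at an independent uniform position, same cluster
    has_par = rng.random(n_genes) < cfg.paralog_prob

    strand = np.where(rng.random(n_genes) < 0.5, "+", "-")
    genome_arr = np.array(genome_ids)[gi]
    gene_id = np.char.add(np.char.add(genome_arr.astype(str), "_"),
                          cluster_ids[ci].astype(str))
    cat_names = np.array(_CATS)[cat_g]
    chrom_arr = np.where(chr1_g, "chr1", "chr2")

    genes = pd.DataFrame({
        "gene_id": gene_id,
        "genome_id": genome_arr,
        "chrom_id": chrom_arr,
        "start_bp": start,
        "end_bp": end,
        "strand": strand,
        "cluster_id": cluster_ids[ci],
        "category": cat_names,
    })
    half = np.where(dist * 4 < L, "upper", "lower")
    k = cfg.dosage_exponent_k
    dosage = np.where(chr1_g | (not cfg.chr2_dosage_flat),
                      np.exp2(k * (1.0 - u)), 1.0)
    truth = pd.DataFrame({
        "gene_id": gene_id,
        "genome_id": genome_arr,
        "chrom_id": chrom_arr,
        "category": cat_names,
        "u": u,
        "half": half,
        "expected_dosage_fast": dosage,
    })

    if has_par.any():
        idx = np.nonzero(has_par)[0]
        u2 = rng.random(len(idx))  # paralog copies placed uniformly
        side2 = np.where(rng.random(len(idx)) < 0.5, 1, -1)
        dist2 = np.rint(u2 * (L[idx] / 2.0)).astype(np.int64)
        pos2 = (ori[idx] + side2 * dist2) % L[idx]
        len2 = length[idx]
        start2 = (pos2 - len2 // 2) % L[idx]
        par = genes.iloc[idx].copy()
        par["gene_id"] = par["gene_id"] + "b"
        par["start_bp"] = start2
        par["end_bp"] = (start2 + len2) % L[idx]
        genes = pd.concat([genes, par], ignore_index=True)
        par_truth = truth.iloc[idx].copy()
        par_truth["gene_id"] = par_truth["gene_id"] + "b"
        par_truth["u"] = u2
        par_truth["half"] = np.where(dist2 * 4 < L[idx], "upper", "lower")
        par_truth["expected_dosage_fast"] = np.where(
            (chrom_arr[idx] == "chr1") | (not cfg.chr2_dosage_flat),
            np.exp2(k * (1.0 - u2)), 1.0)
        truth = pd.concat([truth, par_truth], ignore_index=True)

    counts = present.astype(np.int64)
    np.add.at(counts, (ci[has_par], gi[has_par]), 1)
    matrix = PangenomeMatrix(
        pd.DataFrame(counts, index=cluster_ids, columns=genome_ids)
    )
    return SyntheticDataset(
        config=cfg, chromosomes=[chr1, chr2], genes=genes, matrix=matrix, truth=truth
    )


def simulate_counts(
    dataset: SyntheticDataset,
    condition: str = "fast",
    genome_id: str | None = None,
    replicate: int = 0,
) -> pd.Series:
    """Poisson read counts for one genome under fast or slow growth.

    Expected expression per gene is
    ``baseline(category) * 2**(k_eff * (1 - u)) * exp(eps)`` with
    ``k_eff = dosage_exponent_k`` at fast growth and 0 at slow growth
    (plus any configured residual slow-growth gradients), flat on Chr 2.
    Rates are scaled so total counts are about ``library_size``.
    """
    if condition not in ("fast", "slow"):
        raise ValueError("condition must be 'fast' or 'slow'")
    cfg = dataset.config
    genome_id = genome_id or dataset.genome_ids[0]
    genes = dataset.genes_of(genome_id)
    truth = dataset.truth[dataset.truth["genome_id"] == genome_id].set_index("gene_id")
    truth = truth.loc[genes["gene_id"]]

    rng = np.random.default_rng(
        [cfg.seed % (2**31), 202, 0 if condition == "fast" else 1, replicate]
    )
    u = truth["u"].to_numpy()
    cats = truth["category"].to_numpy()
    on_chr1 = truth["chrom_id"].to_numpy() == "chr1"
    k_eff = cfg.dosage_exponent_k if condition == "fast" else 0.0
    dosage = np.where(on_chr1 | (not cfg.chr2_dosage_flat), np.exp2(k_eff * (1 - u)), 1.0)
    if condition == "slow" and cfg.slow_residual_k:
        resid = np.array([cfg.slow_residual_k.get(c, 0.0) for c in cats])
        dosage = dosage * np.where(on_chr1, np.exp2(resid * (1 - u)), 1.0)
    baseline = np.array([cfg.category_baseline[c] for c in cats])
    eps = rng.normal(0.0, cfg.noise_sd_log, len(u))
    expected = baseline * dosage * np.exp(eps)

    span = genes["end_bp"].to_numpy(np.int64) - genes["start_bp"].to_numpy(np.int64)
    chrom_len = np.where(genes["chrom_id"] == "chr1",
                         cfg.chr1_length_bp, cfg.chr2_length_bp)
    span = np.where(span <= 0, span + chrom_len, span)
    rate = expected * span / 1e3
    lam = rate * (cfg.library_size / rate.sum())
    counts = rng.poisson(lam)
    return pd.Series(counts, index=genes["gene_id"], name="read_count")


def truth_report(dataset: SyntheticDataset, path: str | Path) -> None:
    """Write the per-gene truth table (category, u, half, expected dosage)."""
    dataset.truth.to_csv(path, sep="\t", index=False, float_format="%.8g")
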