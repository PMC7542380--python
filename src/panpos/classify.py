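"""Pangene category classification from a cluster-occupancy matrix.

A cluster's *occupancy* is the number of genomes encoding at least one
member (paralogs count once).  With ``N`` genomes the default thresholds
assign:

* **core** — occupancy ``N`` (every genome),
* **softcore** (nested) — occupancy ``>= floor(0.95 * N)`` (includes core),
* **shell** — occupancy strictly between ``cloud_max`` and the softcore
  threshold,
* **cloud** — occupancy ``<= cloud_max`` (default 2).

With ``N = 124`` this reproduces the boundaries core=124, softcore>=117,
shell 3–116, cloud<=2.  The *exclusive* view subtracts core from softcore
so the four categories partition the clusters; distribution and expression
reporting uses the exclusive view by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CATEGORIES",
    "PangenomeMatrix",
    "CategoryThresholds",
    "occupancy",
    "softcore_threshold",
    "classify_cluster",
    "classify_all",
    "attach_categories",
]

logger = logging.getLogger(__name__)

#: Category names ordered from most to least prevalent occupancy.
CATEGORIES: tuple[str, ...] = ("core", "softcore", "shell", "cloud")


class PangenomeMatrix:
    """Clusters x genomes matrix of non-negative member counts."""

    def __init__(self, counts: pd.DataFrame):
        if counts.shape[1] < 1:
            raise ValueError("need at least one genome")
        arr = counts.to_numpy()
        if (arr < 0).any():
            raise ValueError("negative cell in pangenome matrix")
        if (arr.sum(axis=1) == 0).any():
            empty = counts.index[arr.sum(axis=1) == 0][0]
            raise ValueError(f"cluster {empty!r} has no members in any genome")
        self.counts = counts

    @property
    def cluster_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def genome_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genomes(self) -> int:
        return self.counts.shape[1]

    def occupancies(self) -> pd.Series:
        """Occupancy of every cluster (genomes with >= 1 member)."""
        return (self.counts >= 1).sum(axis=1).rename("occupancy")

    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t")

    def __repr__(self) -> str:  # pragma: no cover
        return f"PangenomeMatrix({len(self.cluster_ids)} clusters x {self.n_genomes} genomes)"


def occupancy(matrix: PangenomeMatrix, cluster_id: str) -> int:
    """Number of genomes encoding at least one member of a cluster.

    Paralogs (cell values > 1) count their genome once.
    """
    if cluster_id not in matrix.counts.index:
        raise KeyError(f"unknown cluster {cluster_id!r}")
    return int((matrix.counts.loc[cluster_id] >= 1).sum())


def softcore_threshold(n_genomes: int, softcore_fraction: float = 0.95) -> int:
    """Minimum occupancy classifying a cluster as softcore: floor(fraction * N)."""
    if n_genomes < 1:
        raise ValueError("n_genomes must be >= 1")
    if not 0 < softcore_fraction <= 1:
        raise ValueError("softcore_fraction must be in (0, 1]")
    return math.floor(softcore_fraction * n_genomes)


@dataclass(frozen=True)
class CategoryThresholds:
    """Occupancy thresholds for the four pangene categories."""

    n_genomes: int
    softcore_fraction: float = 0.95
    cloud_max: int = 2

    def __post_init__(self) -> None:
        sm = self.softcore_min
        if not (self.cloud_max < 3 <= sm <= self.n_genomes):
            raise ValueError(
                f"infeasible thresholds: need cloud_max < 3 <= softcore_min <= N, "
                f"got cloud_max={self.cloud_max}, softcore_min={sm}, N={self.n_genomes}"
            )

    @property
    def softcore_min(self) -> int:
        return softcore_threshold(self.n_genomes, self.softcore_fraction)

    @property
    def shell_max(self) -> int:
        return self.softcore_min - 1


def classify_cluster(occ: int, thr: CategoryThresholds) -> tuple[str, str]:
    """Return ``(category_nested, category_exclusive)`` for one occupancy.

    In the nested view softcore includes core (the clustering-tool
    convention); in the exclusive view core is split out so the four
    categories are disjoint.
    """
    if not 1 <= occ <= thr.n_genomes:
        raise ValueError(f"occupancy {occ} outside [1, {thr.n_genomes}]")
    if occ <= thr.cloud_max:
        return "cloud", "cloud"
    if occ >= thr.softcore_min:
        nested = "softcore"
        exclusive = "core" if occ == thr.n_genomes else "softcore"
        return nested, exclusive
    return "shell", "shell"


def classify_all(
    matrix: PangenomeMatrix, thr: CategoryThresholds | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every cluster; return (assignments, summary).

    assignments: cluster_id, occupancy, category_nested, category_exclusive.
    summary: per category, nested and exclusive counts plus exclusive
    percentages of total clusters (the exclusive view partitions, so its
    percentages sum to 100).
    """
    if thr is None:
        thr = CategoryThresholds(matrix.n_genomes)
    if thr.n_genomes != matrix.n_genomes:
        raise ValueError("thresholds built for a different genome count")
    occ = matrix.occupancies().to_numpy()
    nested = np.where(
        occ <= thr.cloud_max, "cloud", np.where(occ >= thr.softcore_min, "softcore", "shell")
    )
    exclusive = nested.copy()
    exclusive[occ == thr.n_genomes] = "core"
    assignments = pd.DataFrame(
        {
            "cluster_id": matrix.cluster_ids,
            "occupancy": occ,
            "category_nested": nested,
            "category_exclusive": exclusive,
        }
    )
    total = len(assignments)
    rows = []
    for cat in CATEGORIES:
        n_ex = int((exclusive == cat).sum())
        n_ne = n_ex if cat == "core" else int((nested == cat).sum())
        if cat == "softcore":
            n_ne = int((nested == "softcore").sum())  # includes core
        rows.append(
            {
                "category": cat,
                "n_nested": n_ne,
                "n_exclusive": n_ex,
                "pct_exclusive": 100.0 * n_ex / total,
            }
        )
    summary = pd.DataFrame(rows)
    return assignments, summary


def attach_categories(
    genes: pd.DataFrame,
    assignments: pd.DataFrame,
    view: str = "exclusive",
    orphan_policy: str = "drop",
) -> pd.DataFrame:
    """Join pangene categories onto a gene table by cluster_id.

    ``orphan_policy`` controls genes whose cluster is absent from the
    assignments (or that have no cluster at all): ``drop`` removes them with
    a logged warning, ``label`` keeps them as category ``unassigned``,
    ``strict`` raises listing the offending gene ids.
    """
    if view not in ("exclusive", "nested"):
        raise ValueError("view must be 'exclusive' or 'nested'")
    if orphan_policy not in ("drop", "label", "strict"):
        raise ValueError("orphan_policy must be drop|label|strict")
    cat_col = f"category_{view}"
    lut = assignments.set_index("cluster_id")[cat_col]
    cats = genes["cluster_id"].map(lut)
    orphan = cats.isna()
    if orphan.any():
        ids = genes.loc[orphan, "gene_id"].tolist()
        if orphan_policy == "strict":
            raise ValueError(f"{len(ids)} genes without cluster assignment: {ids[:10]}")
        if orphan_policy == "drop":
            logger.warning("dropping %d genes without cluster assignment", len(ids))
            out = genes.loc[~orphan].copy()
            out["category"] = cats[~orphan].to_numpy()
            return out.reset_index(drop=True)
        cats = cats.fillna("unassigned")
    out = genes.copy()
    out["category"] = cats.to_numpy()
    return out
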