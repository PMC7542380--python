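"""Expression gradients along the ori->ter axis.

The pipeline: per-CDS read counts become RPKM
(``count / ((length/1e3) * (total/1e6))`` with the total taken over all CDS
of the genome, both chromosomes), each gene's RPKM is expressed as a log2
ratio to the median RPKM of the dataset (a "global expression map" centred
at 0), a centred sliding-window mean over gene order (default 200 genes,
wrapping across the origin) draws the trend, and per-category upper/lower
quartile tables plus unpaired Wilcoxon rank-sum tests quantify whether
ori-proximal genes are expressed higher.

Genes with zero reads have no finite log2 ratio; they are imputed at
``epsilon = half the smallest nonzero RPKM`` and flagged, kept in quartile
tables (so a category can legitimately show Q1 = 0) but excluded from
slope fits.

Note on naming: the unpaired "Wilcoxon" comparison of two different gene
sets is the two-sample rank-sum (Mann-Whitney) procedure — there is no
pairing between upper-half and lower-half genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .bias import bonferroni
from .classify import CATEGORIES

__all__ = [
    "ExpressionProfile",
    "RankTestResult",
    "compute_rpkm",
    "log2_ratio_map",
    "sliding_trend",
    "quartile_table",
    "rank_test_upper_vs_lower",
    "aggregate_replicates",
    "ExpressionGradient",
    "ExpressionGradientResults",
]


@dataclass
class ExpressionProfile:
    """Per-gene expression table plus dataset-level normalisation constants."""

    data: pd.DataFrame  # gene_id, length_bp, read_count, rpkm [, log2_ratio, imputed]
    total_mapped: int
    median_rpkm: float | None = None
    median_scope: str | None = None
    medians: dict = field(default_factory=dict)


@dataclass(frozen=True)
class RankTestResult:
    """Unpaired two-sample rank-sum comparison of upper vs lower RPKM."""

    statistic: float
    p_value: float
    median_upper: float
    median_lower: float
    n_upper: int
    n_lower: int
    method: str
    p_adjusted: float | None = None


def _gene_lengths(loci: pd.DataFrame) -> pd.Series:
    # length on the circle: end-start, unwrapped when the gene spans the origin
    span = loci["end_bp"].to_numpy(np.int64) - loci["start_bp"].to_numpy(np.int64)
    if "chrom_length_bp" in loci.columns:
        chrom_len = loci["chrom_length_bp"].to_numpy(np.int64)
        span = np.where(span <= 0, span + chrom_len, span)
    elif (span <= 0).any():
        raise ValueError(
            "origin-wrapping gene needs a chrom_length_bp column to compute its length"
        )
    return pd.Series(span, index=loci.index, name="length_bp")


def aggregate_replicates(counts_list: list[pd.Series]) -> pd.Series:
    """Sum read counts over replicate runs of one condition (gene-id aligned)."""
    if not counts_list:
        raise ValueError("no count tables given")
    out = counts_list[0].copy()
    for c in counts_list[1:]:
        out = out.add(c, fill_value=0)
    return out.astype(int)


def compute_rpkm(counts: pd.Series, loci: pd.DataFrame) -> ExpressionProfile:
    """Reads per kilobase per million CDS-mapped reads, for every locus.

    ``total_mapped`` is the sum of counts over all CDS of the genome (both
    chromosomes); genes absent from ``counts`` get count 0.
    """
    lengths = _gene_lengths(loci)
    data = loci[["gene_id"]].copy()
    data["length_bp"] = lengths.to_numpy()
    data["read_count"] = (
        data["gene_id"].map(counts).fillna(0).astype(int).to_numpy()
    )
    total = int(data["read_count"].sum())
    if total == 0:
        raise ValueError("total mapped reads is zero")
    kb = data["length_bp"].to_numpy() / 1e3
    data["rpkm"] = data["read_count"].to_numpy() / (kb * (total / 1e6))
    return ExpressionProfile(data=data, total_mapped=total)


def log2_ratio_map(
    profile: ExpressionProfile,
    loci: pd.DataFrame | None = None,
    median_scope: str = "genome",
) -> ExpressionProfile:
    """Add log2(rpkm / median rpkm) to a profile, centring the map at 0.

    ``median_scope='genome'`` uses one median over all CDS (the default,
    one median per dataset); ``'per_chromosome'`` computes a median per
    chromosome (requires ``loci`` with a chrom_id column).  Zero-RPKM genes
    are imputed at half the smallest nonzero RPKM of their scope and
    flagged in the ``imputed`` column.
    """
    data = profile.data.copy()
    if median_scope == "genome":
        scope = pd.Series("all", index=data.index)
    elif median_scope == "per_chromosome":
        if loci is None or "chrom_id" not in loci.columns:
            raise ValueError("per_chromosome scope needs loci with chrom_id")
        scope = pd.Series(
            data["gene_id"].map(loci.set_index("gene_id")["chrom_id"]).to_numpy(),
            index=data.index,
        )
    else:
        raise ValueError("median_scope must be genome|per_chromosome")

    log2_ratio = np.full(len(data), np.nan)
    imputed = np.zeros(len(data), dtype=bool)
    medians: dict[str, float] = {}
    for key, idx in data.groupby(scope).groups.items():
        rpkm = data.loc[idx, "rpkm"].to_numpy()
        nonzero = rpkm[rpkm > 0]
        if nonzero.size == 0:
            raise ValueError(f"all RPKM zero in scope {key!r}")
        med = float(np.median(rpkm))
        if med <= 0:
            raise ValueError(f"median RPKM not positive in scope {key!r}")
        eps = nonzero.min() / 2.0
        vals = np.where(rpkm > 0, rpkm, eps)
        pos = data.index.get_indexer(idx)
        log2_ratio[pos] = np.log2(vals / med)
        imputed[pos] = rpkm == 0
        medians[str(key)] = med
    data["log2_ratio"] = log2_ratio
    data["imputed"] = imputed
    return ExpressionProfile(
        data=data,
        total_mapped=profile.total_mapped,
        median_rpkm=medians.get("all"),
        median_scope=median_scope,
        medians=medians,
    )


def sliding_trend(values, window: int = 200, circular: bool = True) -> np.ndarray:
    """Centred moving average over a gene-order sequence, one value per gene.

    With ``circular=True`` the window wraps across the ends (the origin of
    the circular chromosome).  For even windows the extra point is taken
    upstream.  Linear (non-circular) mode shrinks the window at the edges.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > n:
        raise ValueError(f"window {window} exceeds number of genes {n}; use a smaller window")
    left = window // 2
    right = window - left - 1
    if circular:
        padded = np.concatenate([x[-left:] if left else x[:0], x, x[:right]])
        kernel = np.ones(window) / window
        return np.convolve(padded, kernel, mode="valid")
    csum = np.concatenate([[0.0], np.cumsum(x)])
    lo = np.maximum(np.arange(n) - left, 0)
    hi = np.minimum(np.arange(n) + right + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def quartile_table(
    rpkm: pd.Series,
    loci: pd.DataFrame,
    condition: str,
    chrom_id: str | None = None,
    categories=CATEGORIES,
) -> pd.DataFrame:
    """Q1/Q2/Q3/Max of RPKM per (category, half), one chromosome at a time.

    Quantiles use linear interpolation between order statistics (position
    ``(n-1) * q``).  Empty cells are emitted with ``n_genes=0`` and missing
    quartiles so the table shape is stable.
    """
    sub = loci if chrom_id is None else loci[loci["chrom_id"] == chrom_id]
    rows = []
    for half in ("upper", "lower"):
        for cat in categories:
            ids = sub.loc[(sub["half"] == half) & (sub["category"] == cat), "gene_id"]
            vals = rpkm.reindex(ids).dropna().to_numpy()
            if vals.size:
                q1, q2, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
                mx = float(vals.max())
            else:
                q1 = q2 = q3 = mx = np.nan
            rows.append(
                {
                    "condition": condition,
                    "half": half,
                    "category": cat,
                    "Q1": q1,
                    "Q2": q2,
                    "Q3": q3,
                    "Max": mx,
                    "n_genes": int(vals.size),
                }
            )
    return pd.DataFrame(rows)


def rank_test_upper_vs_lower(upper_rpkms, lower_rpkms) -> RankTestResult:
    """Two-sided unpaired rank-sum test of upper-half vs lower-half RPKM.

    Exact enumeration when both groups have <= 50 values, else the normal
    approximation with tie correction (and continuity correction).
    """
    u = np.asarray(upper_rpkms, dtype=float)
    lo = np.asarray(lower_rpkms, dtype=float)
    if u.size == 0 or lo.size == 0:
        raise ValueError("both groups must be non-empty")
    exact = max(u.size, lo.size) <= 50
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(u, lo, alternative="two-sided", method=method)
    return RankTestResult(
        statistic=float(res.statistic),
        p_value=float(min(1.0, res.pvalue)),
        median_upper=float(np.median(u)),
        median_lower=float(np.median(lo)),
        n_upper=int(u.size),
        n_lower=int(lo.size),
        method=method,
    )


class ExpressionGradient:
    """Model relating per-CDS expression to distance from the replication origin.

    Parameters
    ----------
    counts : Series
        Read counts indexed by gene_id (replicates already aggregated).
    loci : DataFrame
        Located, categorised gene table for the expressed genome.
    condition : str
        Label carried into tables (e.g. ``fast`` or ``slow``).
    """

    def __init__(self, counts: pd.Series, loci: pd.DataFrame, condition: str = "sample"):
        required = {"gene_id", "chrom_id", "start_bp", "end_bp", "half", "rel_dist"}
        if not required <= set(loci.columns):
            raise ValueError(f"loci table needs columns {sorted(required)}")
        self.counts = counts
        self.loci = loci.reset_index(drop=True)
        self.condition = condition

    @classmethod
    def from_counts(cls, counts, loci, condition="sample"):
        return cls(pd.Series(counts) if not isinstance(counts, pd.Series) else counts,
                   loci, condition)

    def fit(
        self,
        window: int = 200,
        median_scope: str = "genome",
        alpha: float = 0.05,
        trend_chrom: str | None = None,
        slope_chrom: str | None = None,
    ) -> "ExpressionGradientResults":
        """Compute RPKM, the log2-ratio map, trends, quartiles and rank tests.

        ``slope_chrom`` restricts the log2-ratio ~ rel_dist regression to one
        chromosome (default: the first chromosome in locus order, the large
        replicon carrying the dosage gradient).
        """
        profile = compute_rpkm(self.counts, self.loci)
        profile = log2_ratio_map(profile, self.loci, median_scope=median_scope)
        merged = self.loci.merge(profile.data, on="gene_id", validate="one_to_one")

        trends: dict[str, pd.DataFrame] = {}
        for chrom, grp in merged.groupby("chrom_id", sort=True):
            if trend_chrom is not None and chrom != trend_chrom:
                continue
            grp = grp.sort_values(["recentred_bp", "gene_id"], kind="mergesort")
            w = min(window, len(grp))
            sm_vals = sliding_trend(grp["log2_ratio"].to_numpy(), window=w, circular=True)
            trends[chrom] = pd.DataFrame(
                {
                    "gene_id": grp["gene_id"].to_numpy(),
                    "recentred_bp": grp["recentred_bp"].to_numpy(),
                    "log2_ratio": grp["log2_ratio"].to_numpy(),
                    "trend": sm_vals,
                }
            )

        chroms = sorted(merged["chrom_id"].unique())
        slope_chrom = slope_chrom or chroms[0]
        fitdat = merged[(merged["chrom_id"] == slope_chrom) & (~merged["imputed"])]
        X = sm.add_constant(fitdat["rel_dist"].to_numpy())
        ols = sm.OLS(fitdat["log2_ratio"].to_numpy(), X).fit()

        rpkm = pd.Series(merged["rpkm"].to_numpy(), index=merged["gene_id"])
        quartiles = quartile_table(rpkm, merged, self.condition, chrom_id=slope_chrom)

        cats = [c for c in CATEGORIES if c in set(merged["category"])] \
            if "category" in merged.columns else []
        tests = []
        for cat in cats:
            sub = merged[(merged["chrom_id"] == slope_chrom) & (merged["category"] == cat)]
            up = sub.loc[sub["half"] == "upper", "rpkm"]
            lo = sub.loc[sub["half"] == "lower", "rpkm"]
            if len(up) == 0 or len(lo) == 0:
                continue
            r = rank_test_upper_vs_lower(up, lo)
            tests.append((cat, r))
        if tests:
            p_adj = bonferroni([r.p_value for _, r in tests])
            tests = [
                (cat, RankTestResult(**{**r.__dict__, "p_adjusted": float(pa)}))
                for (cat, r), pa in zip(tests, p_adj)
            ]

        return ExpressionGradientResults(
            self, profile, merged, trends, ols, slope_chrom, quartiles,
            dict(tests), alpha, window,
        )


class ExpressionGradientResults:
    """Fitted expression gradient: maps, trend, slope, quartiles, rank tests."""

    def __init__(self, model, profile, merged, trends, ols, slope_chrom,
                 quartiles, rank_tests, alpha, window):
        self.model = model
        self.profile = profile
        self.data = merged
        self.trends = trends
        self._ols = ols
        self.slope_chrom = slope_chrom
        self.quartiles = quartiles
        self.rank_tests = rank_tests
        self.alpha = alpha
        self.window = window

    @property
    def slope(self) -> float:
        """Fitted slope of log2(RPKM ratio) vs rel_dist (0 at ori, 1 at ter)."""
        return float(self._ols.params[1])

    @property
    def slope_se(self) -> float:
        return float(self._ols.bse[1])

    @property
    def slope_pvalue(self) -> float:
        return float(self._ols.pvalues[1])

    @property
    def dosage_exponent(self) -> float:
        """Implied dosage exponent k: expression ~ 2^(k * (1 - rel_dist))."""
        return -self.slope

    def rank_test_table(self) -> pd.DataFrame:
        rows = []
        for cat, r in self.rank_tests.items():
            rows.append(
                {
                    "condition": self.model.condition,
                    "category": cat,
                    "statistic": r.statistic,
                    "p_value": r.p_value,
                    "p_adj": r.p_adjusted,
                    "median_upper": r.median_upper,
                    "median_lower": r.median_lower,
                    "n_upper": r.n_upper,
                    "n_lower": r.n_lower,
                    "significant": bool(r.p_adjusted is not None and r.p_adjusted <= self.alpha),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        med = self.profile.median_rpkm
        lines = [
            f"Expression gradient ({self.model.condition})",
            f"total CDS-mapped reads: {self.profile.total_mapped}",
            f"median RPKM: {med:.4g}" if med is not None else "median RPKM: per-chromosome",
            f"log2(RPKM/median) ~ rel_dist on {self.slope_chrom}: "
            f"slope {self.slope:+.4f} +/- {self.slope_se:.4f} (p={self.slope_pvalue:.3g})",
            f"implied dosage exponent k = {self.dosage_exponent:.3f}",
            "",
            "upper vs lower rank-sum tests (Bonferroni-adjusted):",
        ]
        for cat, r in self.rank_tests.items():
            sig = "*" if (r.p_adjusted is not None and r.p_adjusted <= self.alpha) else " "
            lines.append(
                f" {sig} {cat:>9s}: median upper={r.median_upper:10.2f} "
                f"lower={r.median_lower:10.2f} p_adj={r.p_adjusted:.3g}"
            )
        return "\n".join(lines)
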