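"""Upper-half vs lower-half positional bias of pangene categories.

For each (genome, chromosome, category) the genes falling in the
ori-proximal ("upper") and ter-proximal ("lower") halves are counted and a
one-degree-of-freedom chi-square goodness-of-fit test is run against a null
expectation — either a 50:50 split (``uniform``, the default, since the
halves are equal arcs by construction) or the chromosome's overall
upper:lower CDS ratio (``cds_proportional``, which absorbs any global gene
density bias).  P-values are Bonferroni-corrected over the whole scan.

:class:`PositionalBias` wraps the scan as a model object: build it from a
located gene table, call :meth:`~PositionalBias.fit`, and read counts,
test statistics and adjusted significance off the returned
:class:`PositionalBiasResults`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classify import CATEGORIES

__all__ = [
    "BiasTestResult",
    "distribution_counts",
    "chi_square_bias",
    "bonferroni",
    "bias_scan",
    "PositionalBias",
    "PositionalBiasResults",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BiasTestResult:
    """One chi-square half-bias test (unadjusted unless p_adjusted set)."""

    upper: int
    lower: int
    chi2_stat: float
    df: int
    p_value: float
    expected_upper: float
    expected_lower: float
    direction: str  # upper | lower | none
    p_adjusted: float | None = None


def distribution_counts(loci: pd.DataFrame, categories=CATEGORIES) -> pd.DataFrame:
    """Count genes per (genome, chromosome, category, half) with percentages.

    Percentages are of the chromosome's total CDS count, as in per-category
    distribution histograms; over all categories and halves they sum to 100
    per chromosome.
    """
    required = {"genome_id", "chrom_id", "category", "half"}
    if not required <= set(loci.columns):
        raise ValueError(f"loci table needs columns {sorted(required)}")
    chrom_tot = loci.groupby(["genome_id", "chrom_id"], sort=True).size()
    rows = []
    grouped = loci.groupby(["genome_id", "chrom_id", "category"], sort=True)
    counts = {key: grp["half"].value_counts() for key, grp in grouped}
    for genome_id, chrom_id in chrom_tot.index:
        total = chrom_tot[(genome_id, chrom_id)]
        for cat in categories:
            vc = counts.get((genome_id, chrom_id, cat))
            up = int(vc.get("upper", 0)) if vc is not None else 0
            lo = int(vc.get("lower", 0)) if vc is not None else 0
            rows.append(
                {
                    "genome_id": genome_id,
                    "chrom_id": chrom_id,
                    "category": cat,
                    "upper_count": up,
                    "lower_count": lo,
                    "pct_upper_of_chrom_cds": 100.0 * up / total if total else 0.0,
                    "pct_lower_of_chrom_cds": 100.0 * lo / total if total else 0.0,
                }
            )
    return pd.DataFrame(rows)


def chi_square_bias(
    upper: int,
    lower: int,
    expected_mode: str = "uniform",
    background: tuple[int, int] | None = None,
) -> BiasTestResult:
    """One-df chi-square goodness of fit of an (upper, lower) split.

    ``uniform`` expects a 50:50 split; ``cds_proportional`` splits the total
    by the chromosome-wide ``background = (upper_total, lower_total)`` CDS
    ratio.  Expected counts below 5 log a validity warning (an exact test
    would be preferable there) and an expected count of 0 is an error.
    """
    n = upper + lower
    if n < 1:
        raise ValueError("both counts zero: test undefined")
    if expected_mode == "uniform":
        e_up = e_lo = n / 2.0
    elif expected_mode == "cds_proportional":
        if background is None:
            raise ValueError("cds_proportional requires background totals")
        bu, bl = background
        if bu + bl <= 0:
            raise ValueError("background totals must be positive")
        e_up = n * bu / (bu + bl)
        e_lo = n * bl / (bu + bl)
    else:
        raise ValueError("expected_mode must be uniform|cds_proportional")
    if e_up == 0 or e_lo == 0:
        raise ValueError("expected count 0: use an exact test instead")
    if min(e_up, e_lo) < 5:
        logger.warning(
            "expected count %.2f < 5; chi-square approximation may be poor", min(e_up, e_lo)
        )
    chi2 = (upper - e_up) ** 2 / e_up + (lower - e_lo) ** 2 / e_lo
    p = float(stats.chi2.sf(chi2, df=1))
    if upper > e_up:
        direction = "upper"
    elif upper < e_up:
        direction = "lower"
    else:
        direction = "none"
    return BiasTestResult(
        upper=int(upper),
        lower=int(lower),
        chi2_stat=float(chi2),
        df=1,
        p_value=p,
        expected_upper=float(e_up),
        expected_lower=float(e_lo),
        direction=direction,
    )


def bonferroni(p_values) -> np.ndarray:
    """Bonferroni adjustment: each p mapped to min(1, m*p), m = family size."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, len(p) * p)


def bias_scan(
    table: pd.DataFrame,
    alpha: float = 0.05,
    expected_mode: str = "uniform",
) -> pd.DataFrame:
    """Run the half-bias chi-square test for every row of a distribution table.

    The Bonferroni family is all tests executed in the scan (rows with at
    least one gene).  Returns the table extended with chi2, df, p, p_adj,
    direction and a significance flag at ``alpha``.
    """
    table = table.copy()
    bg = {
        key: (int(grp["upper_count"].sum()), int(grp["lower_count"].sum()))
        for key, grp in table.groupby(["genome_id", "chrom_id"], sort=False)
    }
    results: list[BiasTestResult | None] = []
    for row in table.itertuples(index=False):
        if row.upper_count + row.lower_count == 0:
            results.append(None)
            continue
        results.append(
            chi_square_bias(
                row.upper_count,
                row.lower_count,
                expected_mode=expected_mode,
                background=bg[(row.genome_id, row.chrom_id)],
            )
        )
    tested = [r for r in results if r is not None]
    p_adj_iter = iter(bonferroni([r.p_value for r in tested])) if tested else iter([])

    cols = {k: [] for k in ["chi2", "df", "p_value", "p_adj", "direction", "significant"]}
    for r in results:
        if r is None:
            for k in cols:
                cols[k].append(np.nan if k != "direction" else "none")
            cols["significant"][-1] = False
            continue
        pa = float(next(p_adj_iter))
        cols["chi2"].append(r.chi2_stat)
        cols["df"].append(r.df)
        cols["p_value"].append(r.p_value)
        cols["p_adj"].append(pa)
        cols["direction"].append(r.direction)
        cols["significant"].append(bool(pa <= alpha))
    for k, v in cols.items():
        table[k] = v
    return table


class PositionalBias:
    """Model of pangene-category placement relative to the replication origin.

    Parameters
    ----------
    loci : DataFrame
        A located gene table (see :func:`panpos.geometry.locate_genes`) with
        ``genome_id, chrom_id, category, half`` columns.
    """

    def __init__(self, loci: pd.DataFrame):
        required = {"genome_id", "chrom_id", "category", "half"}
        if not required <= set(loci.columns):
            raise ValueError(f"loci table needs columns {sorted(required)}")
        self.loci = loci
        cats = [c for c in CATEGORIES if c in set(loci["category"])]
        extra = sorted(set(loci["category"]) - set(CATEGORIES))
        self.categories = tuple(cats + extra)

    @classmethod
    def from_dataframe(cls, loci: pd.DataFrame) -> "PositionalBias":
        return cls(loci)

    def fit(self, alpha: float = 0.05, expected_mode: str = "uniform") -> "PositionalBiasResults":
        dist = distribution_counts(self.loci, categories=self.categories)
        tests = bias_scan(dist, alpha=alpha, expected_mode=expected_mode)
        return PositionalBiasResults(self, dist, tests, alpha, expected_mode)


class PositionalBiasResults:
    """Fitted half-bias scan: counts, chi-square tests and adjusted flags."""

    def __init__(self, model, distribution, tests, alpha, expected_mode):
        self.model = model
        self.distribution = distribution
        self.tests = tests
        self.alpha = alpha
        self.expected_mode = expected_mode

    @property
    def n_tests(self) -> int:
        return int(self.tests["p_value"].notna().sum())

    def significant(self) -> pd.DataFrame:
        return self.tests[self.tests["significant"]]

    def summary(self) -> str:
        lines = [
            "Positional bias scan (chi-square goodness of fit, df=1)",
            f"null: {self.expected_mode}; alpha={self.alpha}; "
            f"Bonferroni family m={self.n_tests}",
            "",
        ]
        t = self.tests
        for row in t.itertuples(index=False):
            if np.isnan(row.p_value) if isinstance(row.p_value, float) else False:
                continue
            flag = "*" if row.significant else " "
            lines.append(
                f"{flag} {row.genome_id:>10s} {row.chrom_id:>8s} {row.category:>9s} "
                f"upper={row.upper_count:<6d} lower={row.lower_count:<6d} "
                f"chi2={row.chi2:9.3f} p_adj={row.p_adj:.3g} {row.direction}"
            )
        return "\n".join(lines)
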