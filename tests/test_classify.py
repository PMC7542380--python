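import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from panpos.classify import (
    CATEGORIES,
    CategoryThresholds,
    PangenomeMatrix,
    attach_categories,
    classify_all,
    classify_cluster,
    occupancy,
    softcore_threshold,
)

from _oracles import occupancy_brute


def make_matrix(rows: dict[str, list[int]], genomes: list[str]) -> PangenomeMatrix:
    return PangenomeMatrix(pd.DataFrame.from_dict(rows, orient="index", columns=genomes))


class TestSoftcoreThreshold:
    @pytest.mark.parametrize(
        "n,frac,expected",
        [(124, 0.95, 117), (20, 0.95, 19), (124, 1.0, 124), (12, 0.95, 11)],
    )
    def test_floor_rule(self, n, frac, expected):
        assert softcore_threshold(n, frac) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            softcore_threshold(0)
        with pytest.raises(ValueError):
            softcore_threshold(10, 1.5)


class TestClassifyCluster:
    thr124 = CategoryThresholds(124)

    @pytest.mark.parametrize(
        "occ,nested,exclusive",
        [
            (124, "softcore", "core"),
            (117, "softcore", "softcore"),
            (116, "shell", "shell"),
            (3, "shell", "shell"),
            (2, "cloud", "cloud"),
            (1, "cloud", "cloud"),
        ],
    )
    def test_boundaries_at_n_124(self, occ, nested, exclusive):
        assert classify_cluster(occ, self.thr124) == (nested, exclusive)

    def test_occupancy_out_of_range(self):
        with pytest.raises(ValueError):
            classify_cluster(0, self.thr124)
        with pytest.raises(ValueError):
            classify_cluster(125, self.thr124)

    def test_infeasible_thresholds_rejected(self):
        with pytest.raises(ValueError, match="infeasible"):
            CategoryThresholds(2)  # softcore_min = 1 < 3


class TestOccupancy:
    def test_examples(self):
        m = make_matrix({"c1": [1, 1, 1], "c2": [2, 0, 1]}, ["a", "b", "c"])
        assert occupancy(m, "c1") == 3
        assert occupancy(m, "c2") == 2  # paralogs count once

    def test_unknown_cluster(self):
        m = make_matrix({"c1": [1]}, ["a"])
        with pytest.raises(KeyError):
            occupancy(m, "nope")

    def test_against_brute_force(self, rng):
        for _ in range(1000):
            row = rng.integers(0, 4, size=50)
            if row.sum() == 0:
                row[0] = 1
            m = make_matrix({"c": list(row)}, [f"g{i}" for i in range(50)])
            assert occupancy(m, "c") == occupancy_brute(row)


class TestClassifyAll:
    def test_toy_matrix_hand_enumeration(self):
        # occupancies (4,4,3,2,1) over 4 genomes; softcore_min=floor(.95*4)=3,
        # so occupancy 3 is softcore (nested softcore includes the two cores)
        m = make_matrix(
            {
                "c1": [1, 1, 1, 1],
                "c2": [1, 2, 1, 1],
                "c3": [1, 1, 1, 0],
                "c4": [0, 1, 1, 0],
                "c5": [1, 0, 0, 0],
            },
            ["a", "b", "c", "d"],
        )
        assignments, summary = classify_all(m, CategoryThresholds(4))
        s = summary.set_index("category")
        assert s.loc["core", "n_exclusive"] == 2
        assert s.loc["softcore", "n_nested"] == 3  # includes core
        assert s.loc["softcore", "n_exclusive"] == 1
        assert s.loc["shell", "n_exclusive"] == 0
        assert s.loc["cloud", "n_exclusive"] == 2

    def test_all_core(self):
        m = make_matrix({f"c{i}": [1, 1, 1, 1] for i in range(5)}, list("abcd"))
        _, summary = classify_all(m, CategoryThresholds(4))
        s = summary.set_index("category")
        assert s.loc["core", "pct_exclusive"] == 100.0

    def test_exclusive_partition_sums(self, rng, small_dataset):
        assignments, summary = classify_all(small_dataset.matrix)
        assert summary["n_exclusive"].sum() == len(assignments)
        assert summary["pct_exclusive"].sum() == pytest.approx(100.0)
        # nesting identity: softcore(nested) = core + softcore(exclusive)
        s = summary.set_index("category")
        assert (
            s.loc["softcore", "n_nested"]
            == s.loc["core", "n_exclusive"] + s.loc["softcore", "n_exclusive"]
        )
        # nested softcore+shell+cloud also partition all clusters
        assert (
            s.loc["softcore", "n_nested"]
            + s.loc["shell", "n_nested"]
            + s.loc["cloud", "n_nested"]
            == len(assignments)
        )

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        n=st.integers(min_value=5, max_value=200),
        occ_pair=st.tuples(st.integers(1, 200), st.integers(1, 200)),
    )
    def test_monotone_in_occupancy(self, n, occ_pair):
        """Raising occupancy never moves a cluster to a rarer category."""
        thr = CategoryThresholds(n)
        prevalence = {c: i for i, c in enumerate(CATEGORIES)}
        lo, hi = sorted(min(o, n) for o in occ_pair)
        _, cat_lo = classify_cluster(lo, thr)
        _, cat_hi = classify_cluster(hi, thr)
        assert prevalence[cat_hi] <= prevalence[cat_lo]


class TestAttachCategories:
    assignments = pd.DataFrame(
        {
            "cluster_id": ["c1", "c2"],
            "occupancy": [3, 1],
            "category_nested": ["softcore", "cloud"],
            "category_exclusive": ["core", "cloud"],
        }
    )

    def genes(self):
        return pd.DataFrame(
            {
                "gene_id": ["g1", "g2", "g3"],
                "genome_id": "G",
                "chrom_id": "chr",
                "start_bp": [0, 10, 20],
                "end_bp": [9, 19, 29],
                "strand": "+",
                "cluster_id": ["c1", "c2", None],
            }
        )

    def test_join_and_views(self):
        out = attach_categories(self.genes(), self.assignments, view="nested",
                                orphan_policy="label")
        assert list(out["category"]) == ["softcore", "cloud", "unassigned"]
        out = attach_categories(self.genes(), self.assignments, orphan_policy="label")
        assert list(out["category"]) == ["core", "cloud", "unassigned"]

    def test_orphan_drop_and_strict(self):
        out = attach_categories(self.genes(), self.assignments, orphan_policy="drop")
        assert list(out["gene_id"]) == ["g1", "g2"]
        with pytest.raises(ValueError, match="g3"):
            attach_categories(self.genes(), self.assignments, orphan_policy="strict")

    def test_join_matches_dict_lookup(self, small_dataset):
        assignments, _ = classify_all(small_dataset.matrix)
        genes = small_dataset.genes.drop(columns=["category"]).head(100)
        out = attach_categories(genes, assignments)
        lut = dict(zip(assignments["cluster_id"], assignments["category_exclusive"]))
        expected = [lut[c] for c in genes["cluster_id"]]
        assert list(out["category"]) == expected
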