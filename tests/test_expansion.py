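import numpy as np
import pandas as pd
import pytest

from tcr_clonoscope.expansion import (
    EXPANDED_MIN_SIZE,
    clone_size_spectrum,
    cluster_expansion_enrichment,
    composition_by_clone_size,
    downsample_compare,
    mean_clone_size,
    strata_percentages,
)
from tcr_clonoscope.simulate import CloneSizeLaw, clonotype_ids_from_law


def _cells(ids, sample="S1", cluster="C1", condition="PD"):
    """Cell table from a flat clonotype-id list (None = NA stratum)."""
    ids = list(ids)
    sizes = pd.Series([i for i in ids if i is not None]).value_counts()
    return pd.DataFrame(
        {
            "barcode": [f"b{i}" for i in range(len(ids))],
            "sample_id": sample,
            "condition": condition,
            "tissue": "blood",
            "cluster": cluster,
            "clonotype_id": ids,
            "clone_size": [np.nan if i is None else sizes[i] for i in ids],
            "has_ab": [i is not None for i in ids],
        }
    )


class TestSpectrum:
    def test_basic(self):
        cells = _cells(["a", "a", "a", "b", "b", "c", None])
        sp = clone_size_spectrum(cells)
        assert sp.counts == {1: 1, 2: 1, 3: 1}
        assert sp.n_cells == 6 and sp.n_clonotypes == 3

    def test_restriction_recomputes_sizes(self):
        cells = _cells(["a", "a", "b"])
        mask = cells["barcode"].isin(["b0", "b2"])
        sp = clone_size_spectrum(cells, restrict=mask.to_numpy())
        # clone "a" contributes at its within-subset size 1
        assert sp.counts == {1: 2}

    def test_empty_subset(self):
        sp = clone_size_spectrum(_cells([None, None]))
        assert sp.counts == {} and sp.n_cells == 0

    def test_conservation(self, default_cells):
        sp = clone_size_spectrum(default_cells)
        assert sp.n_cells == int(default_cells["clonotype_id"].notna().sum())
        assert sp.n_clonotypes == default_cells["clonotype_id"].nunique()


class TestDownsample:
    def test_identical_groups_all_p_one(self):
        ids = np.repeat([f"c{i}" for i in range(40)], [3] * 10 + [1] * 30)
        res = downsample_compare(ids, ids.copy(), n_iter=10, seed=5)
        assert np.all(res.p_values == 1.0)
        assert res.median_p == 1.0
        assert res.n_drawn == ids.size

    def test_argument_order_symmetry(self):
        rng = np.random.default_rng(3)
        a = clonotype_ids_from_law(CloneSizeLaw(p=0.5), 400, rng, "a")
        b = clonotype_ids_from_law(CloneSizeLaw(p=0.8, heavy_cell_frac=0.1), 700, rng, "b")
        r1 = downsample_compare(a, b, n_iter=15, seed=9)
        r2 = downsample_compare(b, a, n_iter=15, seed=9)
        np.testing.assert_array_equal(r1.p_values, r2.p_values)
        assert r1.n_drawn == r2.n_drawn == 400

    def test_seed_reproducibility_and_sensitivity(self):
        rng = np.random.default_rng(3)
        a = clonotype_ids_from_law(CloneSizeLaw(p=0.6), 3000, rng, "a")
        b = clonotype_ids_from_law(CloneSizeLaw(p=0.65), 5000, rng, "b")
        r1 = downsample_compare(a, b, n_iter=10, seed=1)
        r2 = downsample_compare(a, b, n_iter=10, seed=1)
        r3 = downsample_compare(a, b, n_iter=10, seed=2)
        np.testing.assert_array_equal(r1.p_values, r2.p_values)
        assert not np.array_equal(r1.p_values, r3.p_values)

    def test_single_bin_iteration_is_nan(self):
        a = np.array([f"a{i}" for i in range(10)])  # all singletons
        b = np.array([f"b{i}" for i in range(10)])
        res = downsample_compare(a, b, n_iter=3, seed=0)
        assert np.isnan(res.p_values).all()
        assert np.isnan(res.median_p)

    def test_equal_size_groups_constant_across_iterations(self):
        rng = np.random.default_rng(0)
        a = clonotype_ids_from_law(CloneSizeLaw(p=0.6), 300, rng, "a")
        b = clonotype_ids_from_law(CloneSizeLaw(p=0.6), 300, rng, "b")
        res = downsample_compare(a, b, n_iter=20, seed=4)
        assert np.unique(res.p_values).size == 1  # every draw is the full group

    def test_validation(self):
        with pytest.raises(ValueError, match="non-empty"):
            downsample_compare(np.array([]), np.array(["a"]))
        with pytest.raises(ValueError, match="n_iter"):
            downsample_compare(np.array(["a"]), np.array(["b"]), n_iter=0)


class TestStrata:
    def test_worked_example(self):
        # 10 cells: 2 NA, 4 singletons, 4 in one expanded clone
        ids = [None, None, "s1", "s2", "s3", "s4", "e", "e", "e", "e"]
        strata = strata_percentages(_cells(ids))
        cum = strata["cumulative"].loc["S1"]
        assert cum["NA"] == pytest.approx(20.0)
        assert cum["=1"] == pytest.approx(40.0)
        assert cum[">=2"] == pytest.approx(40.0)
        assert cum[">=20"] == 0.0 and cum[">=100"] == 0.0

    def test_disjoint_rows_sum_to_100(self, default_cells):
        disjoint = strata_percentages(default_cells)["disjoint"]
        np.testing.assert_allclose(disjoint.sum(axis=1), 100.0)

    def test_cumulative_nesting(self, default_cells):
        cum = strata_percentages(default_cells)["cumulative"]
        assert (cum[">=2"] >= cum[">=20"]).all()
        assert (cum[">=20"] >= cum[">=100"]).all()

    def test_large_clone_lands_in_top_stratum(self):
        ids = ["big"] * 120 + ["s1"]
        cum = strata_percentages(_cells(ids))["cumulative"].loc["S1"]
        assert cum[">=100"] == pytest.approx(100 * 120 / 121)


class TestEnrichment:
    def _two_cluster_cells(self):
        # C6: PD 30 expanded / 10 not; HC 10 expanded / 30 not
        # C1: balanced
        rows = []
        k = 0

        def add(n, cluster, condition, expanded):
            nonlocal k
            for _ in range(n):
                rows.append(
                    {
                        "barcode": f"b{k}",
                        "sample_id": "P1" if condition == "PD" else "N1",
                        "condition": condition,
                        "tissue": "blood",
                        "cluster": cluster,
                        "clonotype_id": f"e{k}" if expanded else f"s{k}",
                        "clone_size": 5 if expanded else 1,
                        "has_ab": True,
                    }
                )
                k += 1

        add(30, "C6", "PD", True)
        add(10, "C6", "PD", False)
        add(10, "C6", "HC", True)
        add(30, "C6", "HC", False)
        for cond in ("PD", "HC"):
            add(20, "C1", cond, True)
            add(20, "C1", cond, False)
        return pd.DataFrame(rows)

    def test_condition_by_expanded_design(self):
        from scipy.stats import fisher_exact

        res = cluster_expansion_enrichment(self._two_cluster_cells())
        r6 = res.set_index("cluster").loc["C6"]
        assert (r6["a_expanded"], r6["a_not"], r6["b_expanded"], r6["b_not"]) == (30, 10, 10, 30)
        want_odds, want_p = fisher_exact([[30, 10], [10, 30]], alternative="two-sided")
        assert r6["odds_ratio"] == pytest.approx(want_odds)
        assert r6["p_value"] == pytest.approx(want_p)
        r1 = res.set_index("cluster").loc["C1"]
        assert r1["odds_ratio"] == pytest.approx(1.0)
        assert r1["p_value"] == pytest.approx(1.0)
        assert res.iloc[0]["cluster"] == "C6"  # sorted by FDR

    def test_fdr_bounds_and_monotonicity(self):
        res = cluster_expansion_enrichment(self._two_cluster_cells())
        assert ((res["fdr"] >= res["p_value"] - 1e-12) & (res["fdr"] <= 1.0)).all()

    def test_within_condition_design(self):
        res = cluster_expansion_enrichment(self._two_cluster_cells(), design="within_condition")
        r6 = res.set_index("cluster").loc["C6"]
        # PD cells only: C6 has 30/10, the rest (C1) 20/20
        assert (r6["a_expanded"], r6["a_not"], r6["b_expanded"], r6["b_not"]) == (30, 10, 20, 20)

    def test_degenerate_cluster_flagged(self):
        cells = _cells(["a", "a", "b"], condition="PD")  # no HC cells at all
        res = cluster_expansion_enrichment(cells)
        assert bool(res["degenerate"].all())
        assert (res["p_value"] == 1.0).all()

    def test_unknown_design(self):
        with pytest.raises(ValueError, match="design"):
            cluster_expansion_enrichment(self._two_cluster_cells(), design="bogus")


class TestMeanCloneSize:
    def test_printed_pd_counts(self):
        ids = np.repeat([f"c{i}" for i in range(371)], self._sizes(2301, 371))
        assert mean_clone_size(_cells(ids)) == pytest.approx(2301 / 371)

    def test_printed_hc_counts(self):
        ids = np.repeat([f"c{i}" for i in range(258)], self._sizes(829, 258))
        assert mean_clone_size(_cells(ids)) == pytest.approx(829 / 258)

    @staticmethod
    def _sizes(n_cells, n_clonotypes):
        base = n_cells // n_clonotypes
        sizes = [base] * n_clonotypes
        for i in range(n_cells - base * n_clonotypes):
            sizes[i] += 1
        return sizes

    def test_errors(self):
        with pytest.raises(ValueError, match="empty"):
            mean_clone_size(_cells([]))
        with pytest.raises(ValueError, match="unclonotyped"):
            mean_clone_size(_cells(["a", None]))


def test_composition_fractions_sum_to_one(default_cells):
    comp = composition_by_clone_size(default_cells)
    sums = comp.groupby(["sample_id", "stratum"])["fraction"].sum()
    np.testing.assert_allclose(sums, 1.0)
    assert comp["n_cells"].sum() == int(default_cells["cluster"].notna().sum())


def test_expanded_threshold_is_two():
    assert EXPANDED_MIN_SIZE == 2
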