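import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from selnet.connectivity import (
    compare_mean_connectivity,
    connectivity_profile,
    cull_network,
    differential_connectivity,
    identify_hubs,
)


def _adj(a, ids=None):
    ids = ids or [f"g{i}" for i in range(a.shape[0])]
    return pd.DataFrame(a, index=ids, columns=ids)


class TestCulling:
    def test_equal_connectivity_retains_ninety_of_hundred(self):
        k = pd.Series(1.0, index=[f"g{i}" for i in range(100)])
        assert len(cull_network(k, 0.90)) == 90

    def test_hand_cumulative_sum_toy(self):
        k = pd.Series([10, 5, 3, 1, 1], index=list("abcde"))
        kept = cull_network(k, 0.90)
        assert kept == ["a", "b", "c"]

    def test_keep_fraction_one_is_identity(self):
        k = pd.Series([3.0, 2.0, 1.0], index=list("abc"))
        assert set(cull_network(k, 1.0)) == {"a", "b", "c"}

    def test_invalid_fraction_rejected(self):
        k = pd.Series([1.0], index=["a"])
        for bad in (0.0, -0.5, 1.5):
            with pytest.raises(ValueError):
                cull_network(k, bad)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1e6), min_size=1,
                    max_size=40),
           st.floats(min_value=0.05, max_value=1.0))
    def test_retained_set_carries_at_least_keep_fraction(self, ks, frac):
        k = pd.Series(ks, index=[f"g{i}" for i in range(len(ks))])
        kept = cull_network(k, frac)
        assert k[kept].sum() >= frac * k.sum() - 1e-9


class TestConnectivityProfile:
    def test_star_graph(self):
        n = 6
        a = np.zeros((n, n))
        a[0, 1:] = a[1:, 0] = 1.0
        modules = pd.Series("m1", index=[f"g{i}" for i in range(n)])
        ct = connectivity_profile(_adj(a), modules, "HIGH")
        assert ct.loc["g0", "k_total"] == n - 1
        assert (ct.loc[ct.index[1:], "k_total"] == 1.0).all()
        assert ct.loc["g0", "k_rel"] == 1.0

    def test_weighted_toy_row_sums(self):
        a = np.array([[1, 0.5, 0.2, 0.0],
                      [0.5, 1, 0.1, 0.3],
                      [0.2, 0.1, 1, 0.4],
                      [0.0, 0.3, 0.4, 1]])
        modules = pd.Series(["m1", "m1", "m2", "m2"],
                            index=[f"g{i}" for i in range(4)])
        ct = connectivity_profile(_adj(a), modules, "LOW")
        assert ct.loc["g0", "k_total"] == pytest.approx(0.7)
        assert ct.loc["g0", "k_within"] == pytest.approx(0.5)
        assert ct.loc["g2", "k_within"] == pytest.approx(0.4)
        assert (ct["k_within"] <= ct["k_total"] + 1e-12).all()

    def test_max_gene_per_module_has_k_rel_one(self, rng):
        a = np.abs(rng.normal(size=(20, 20)))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        modules = pd.Series(["m1"] * 10 + ["m2"] * 10,
                            index=[f"g{i}" for i in range(20)])
        ct = connectivity_profile(_adj(a), modules, "HIGH")
        assert ct.groupby("module")["k_rel"].max().eq(1.0).all()


class TestHubs:
    def test_top_gene_flagged_in_module_of_ten(self, rng):
        a = np.abs(rng.normal(size=(10, 10)))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        modules = pd.Series("m1", index=[f"g{i}" for i in range(10)])
        ct = identify_hubs(connectivity_profile(_adj(a), modules, "H"), 0.9)
        assert ct["hub"].sum() == 1
        assert ct.loc[ct["k_within"].idxmax(), "hub"]

    def test_lowering_quantile_never_removes_hubs(self, rng):
        a = np.abs(rng.normal(size=(15, 15)))
        a = (a + a.T) / 2
        modules = pd.Series("m1", index=[f"g{i}" for i in range(15)])
        ct = connectivity_profile(_adj(a), modules, "H")
        hubs_90 = set(identify_hubs(ct, 0.9).query("hub").index)
        hubs_70 = set(identify_hubs(ct, 0.7).query("hub").index)
        assert hubs_90 <= hubs_70


class TestDifferentialConnectivity:
    def _cts(self):
        idx = [f"g{i}" for i in range(4)]
        h = pd.DataFrame({"k_rel": [0.3, 0.9, 0.5, 0.2], "hub": [False] * 4,
                          "k_total": [1, 2, 3, 4.0], "k_within": [1, 2, 3, 4.0],
                          "module": "m1", "line": "HIGH"}, index=idx)
        l = pd.DataFrame({"k_rel": [0.9, 0.9, 0.5, 0.1], "hub": [True] * 4,
                          "k_total": [1, 2, 3, 4.0], "k_within": [1, 2, 3, 4.0],
                          "module": "m1", "line": "LOW"}, index=idx)
        return h, l

    def test_identical_tables_empty(self):
        h, _ = self._cts()
        assert differential_connectivity(h, h).empty

    def test_forced_flag_and_direction(self):
        h, l = self._cts()
        out = differential_connectivity(h, l, 0.5)
        assert list(out.index) == ["g0"]
        assert out.loc["g0", "direction"] == "LOW>HIGH"
        assert out.loc["g0", "delta"] == pytest.approx(0.6)
        assert bool(out.loc["g0", "hub_in_higher_line"])

    def test_swapping_lines_flips_direction(self):
        h, l = self._cts()
        a = differential_connectivity(h, l, 0.5)
        b = differential_connectivity(l, h, 0.5)
        assert set(a.index) == set(b.index)
        assert a.loc["g0", "direction"] != b.loc["g0", "direction"]

    def test_planted_rewired_genes_lose_relative_connectivity(self,
                                                              planted_sim):
        from selnet.coexpression import adjacency_matrix, correlation_matrix
        from selnet.normalize import filter_by_cpm, upper_quartile_normalize

        cm, gt = planted_sim
        ne = filter_by_cpm(upper_quartile_normalize(cm))
        modules = gt.module_labels.loc[ne.gene_ids].map("m{}".format)
        cts = {}
        for ln in ("HIGH", "LOW"):
            adj = adjacency_matrix(correlation_matrix(ne, ln), 6)
            cts[ln] = identify_hubs(connectivity_profile(adj, modules, ln))
        dc = differential_connectivity(cts["HIGH"], cts["LOW"], 0.5)
        flagged = set(dc.index)
        frac_planted_flagged = len(flagged & gt.dw_genes) / len(gt.dw_genes)
        background = len(flagged - gt.dw_genes) / (len(ne.gene_ids)
                                                   - len(gt.dw_genes))
        assert frac_planted_flagged > 4 * background


class TestCompareMeans:
    def test_identical_tables_p_near_one(self):
        idx = [f"g{i}" for i in range(20)]
        ct = pd.DataFrame({"k_total": np.linspace(1, 5, 20),
                           "k_within": np.linspace(0.5, 2, 20)}, index=idx)
        mh, ml, p = compare_mean_connectivity(ct, ct, "total")
        assert mh == ml
        assert p == pytest.approx(1.0)

    def test_globally_damped_line_detected(self, rng):
        idx = [f"g{i}" for i in range(1000)]
        k = np.abs(rng.normal(5, 1, size=1000))
        h = pd.DataFrame({"k_total": k, "k_within": k}, index=idx)
        l = pd.DataFrame({"k_total": 0.5 * k + rng.normal(0, 0.01, 1000),
                          "k_within": k}, index=idx)
        mh, ml, p = compare_mean_connectivity(h, l, "total")
        assert mh > ml and p < 1e-10

    def test_swap_symmetry(self, rng):
        idx = [f"g{i}" for i in range(50)]
        h = pd.DataFrame({"k_total": np.abs(rng.normal(3, 1, 50)),
                          "k_within": np.ones(50)}, index=idx)
        l = pd.DataFrame({"k_total": np.abs(rng.normal(2, 1, 50)),
                          "k_within": np.ones(50)}, index=idx)
        mh1, ml1, p1 = compare_mean_connectivity(h, l, "total")
        mh2, ml2, p2 = compare_mean_connectivity(l, h, "total")
        assert (mh1, ml1) == (ml2, mh2)
        assert p1 == pytest.approx(p2)

    def test_small_subset_p_missing(self):
        idx = [f"g{i}" for i in range(5)]
        ct = pd.DataFrame({"k_total": range(5), "k_within": range(5)},
                          index=idx, dtype=float)
        _, _, p = compare_mean_connectivity(ct, ct, "total")
        assert np.isnan(p)
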