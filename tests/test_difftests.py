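import numpy as np
import pandas as pd
import pytest

from selnet.cosplicing import ExonUsageProfile, exon_proportions
from selnet.data import NormalizedExpression
from selnet.difftests import (
    _changed_edge_counts,
    differential_expression,
    differential_splicing,
    differential_wiring,
    differential_wiring_cosplicing,
)
from selnet.normalize import filter_by_cpm, upper_quartile_normalize
from selnet.simulate import SimulationConfig, simulate_count_dataset, simulate_exon_dataset


def _ne(x: pd.DataFrame, lines) -> NormalizedExpression:
    meta = pd.DataFrame({"line": lines, "region": ["X"] * x.shape[1]},
                        index=x.columns)
    return NormalizedExpression(cpm=2.0**x, log2cpm=x, scale_factors=None,
                                meta=meta)


class TestDifferentialExpression:
    def test_identical_gene_has_zero_fc_and_flat_flag(self, rng):
        x = pd.DataFrame(rng.normal(size=(3, 12)),
                         index=["a", "b", "c"],
                         columns=[f"s{i}" for i in range(12)])
        x.loc["b"] = 5.0
        ne = _ne(x, ["HIGH"] * 6 + ["LOW"] * 6)
        de = differential_expression(ne)
        assert de.loc["b", "p"] == 1.0 and de.loc["b", "log2fc"] == 0.0
        assert bool(de.loc["b", "flat"])

    def test_null_pvalues_approximately_uniform(self, rng):
        x = pd.DataFrame(rng.normal(size=(500, 48)),
                         columns=[f"s{i}" for i in range(48)])
        x.index = [f"g{i}" for i in range(500)]
        ne = _ne(x, ["HIGH"] * 24 + ["LOW"] * 24)
        de = differential_expression(ne)
        assert (de["p"] < 0.05).mean() == pytest.approx(0.05, abs=0.03)
        assert (de["fdr"] < 0.05).mean() <= 0.05
        assert (de["fdr"] >= de["p"] - 1e-12).all()

    def test_planted_log2fc_recovered_with_high_sensitivity(self, planted_sim):
        cm, gt = planted_sim
        ne = filter_by_cpm(upper_quartile_normalize(cm))
        de = differential_expression(ne)
        planted = sorted(gt.de_genes)
        assert (de.loc[planted, "fdr"] < 0.05).mean() >= 0.8
        # directions split as planted
        signs = np.sign(gt.de_log2fc[planted])
        assert (np.sign(de.loc[planted, "log2fc"]) == signs).mean() > 0.9

    def test_direction_consistent_with_sign(self, planted_sim):
        cm, _ = planted_sim
        ne = filter_by_cpm(upper_quartile_normalize(cm))
        de = differential_expression(ne)
        up = de["log2fc"] >= 0
        assert (de.loc[up, "direction"] == "HIGH>LOW").all()
        assert (de.loc[~up, "direction"] == "LOW>HIGH").all()


class TestDifferentialWiring:
    def test_forced_three_gene_edge_change(self):
        # edge (0,1) changes by 0.8 on the unsigned scale; all else equal
        ch = np.array([[1.0, 0.9, 0.2], [0.9, 1.0, 0.2], [0.2, 0.2, 1.0]])
        cl = np.array([[1.0, 0.1, 0.2], [0.1, 1.0, 0.2], [0.2, 0.2, 1.0]])
        counts = _changed_edge_counts(ch, cl, 0.5)
        assert counts.tolist() == [1, 1, 0]

    def test_incidence_total_is_twice_edge_count(self, rng):
        a = np.clip((lambda m: (m + m.T) / 2)(rng.uniform(-1, 1, (20, 20))), -1, 1)
        b = np.clip((lambda m: (m + m.T) / 2)(rng.uniform(-1, 1, (20, 20))), -1, 1)
        counts = _changed_edge_counts(a, b, 0.5)
        d = np.abs(np.abs(a) - np.abs(b))
        np.fill_diagonal(d, 0.0)
        n_edges = (d[np.triu_indices(20, 1)] >= 0.5).sum()
        assert counts.sum() == 2 * n_edges

    def test_pvalues_bounded_below_by_permutation_floor(self, planted_sim):
        cm, _ = planted_sim
        ne = filter_by_cpm(upper_quartile_normalize(cm))
        sub = ne.log2cpm.iloc[:80]
        dw = differential_wiring(sub[ne.samples_of("HIGH")],
                                 sub[ne.samples_of("LOW")],
                                 n_perm=199, seed=5)
        assert (dw["p"] >= 1.0 / 200 - 1e-12).all()
        assert (dw["p"] <= 1.0).all()

    def test_null_data_flags_nothing(self):
        cfg = SimulationConfig(n_genes=200, n_modules=4, module_sizes=[50] * 4,
                               de_fraction=0.0, dw_gene_fraction=0.0,
                               ds_gene_fraction=0.0, seed=31)
        cm, _ = simulate_count_dataset(cfg)
        ne = filter_by_cpm(upper_quartile_normalize(cm))
        dw = differential_wiring(ne.log2cpm[ne.samples_of("HIGH")],
                                 ne.log2cpm[ne.samples_of("LOW")],
                                 n_perm=200, seed=3)
        assert (dw["fdr"] < 0.05).mean() <= 0.05

    def test_planted_rewiring_recovered(self, planted_sim):
        cm, gt = planted_sim
        ne = filter_by_cpm(upper_quartile_normalize(cm))
        dw = differential_wiring(ne.log2cpm[ne.samples_of("HIGH")],
                                 ne.log2cpm[ne.samples_of("LOW")],
                                 n_perm=2000, seed=11)
        planted = sorted(gt.dw_genes)
        assert (dw.loc[planted, "fdr"] < 0.05).mean() >= 0.8

    def test_bad_threshold_rejected(self, rng):
        x = pd.DataFrame(rng.normal(size=(5, 10)))
        with pytest.raises(ValueError):
            differential_wiring(x, x.copy(), delta_threshold=1.5, n_perm=100)


class TestDifferentialSplicing:
    def _profiles(self, hi_props, lo_props):
        """Build per-gene profiles from per-line exon proportion vectors."""
        n = 12
        samples = [f"H{i}" for i in range(n)] + [f"L{i}" for i in range(n)]
        profiles = {}
        for gene, (ph, pl) in enumerate(zip(hi_props, lo_props)):
            cols = {s: list(ph) for s in samples[:n]}
            cols.update({s: list(pl) for s in samples[n:]})
            props = pd.DataFrame(cols, index=[f"e{k}" for k in range(len(ph))])
            profiles[f"g{gene}"] = ExonUsageProfile(
                f"g{gene}", props, pd.Series(True, index=samples)
            )
        meta = pd.DataFrame({"line": ["HIGH"] * n + ["LOW"] * n,
                             "region": ["X"] * 2 * n},
                            index=pd.Index(samples, name="sample_id"))
        return profiles, meta

    def test_statistic_definition_forced_case(self):
        """2-exon gene with line means (0.8,0.2) vs (0.2,0.8): D = 0.6."""
        profiles, meta = self._profiles([(0.8, 0.2)], [(0.2, 0.8)])
        ds = differential_splicing(profiles, meta, n_perm=100, seed=1)
        assert ds.loc["g0", "statistic"] == pytest.approx(0.6, abs=1e-12)

    def test_identical_line_means_give_zero_statistic(self):
        profiles, meta = self._profiles([(0.5, 0.3, 0.2)], [(0.5, 0.3, 0.2)])
        ds = differential_splicing(profiles, meta, n_perm=100, seed=1)
        assert ds.loc["g0", "statistic"] == 0.0
        assert ds.loc["g0", "p"] == 1.0

    def test_invariance_to_exon_relabeling_and_sample_order(self):
        cfg = SimulationConfig(n_genes=40, ds_gene_fraction=0.2, seed=17,
                               dw_gene_fraction=0.0)
        ect, _ = simulate_exon_dataset(cfg)
        profiles = exon_proportions(ect)
        base = differential_splicing(profiles, ect.meta, n_perm=150, seed=2)
        shuffled = {}
        rng = np.random.default_rng(0)
        for g, prof in profiles.items():
            exon_perm = rng.permutation(prof.n_exons)
            props = prof.proportions.iloc[exon_perm]
            shuffled[g] = ExonUsageProfile(g, props, prof.mask)
        again = differential_splicing(shuffled, ect.meta, n_perm=150, seed=2)
        pd.testing.assert_series_equal(base["statistic"], again["statistic"])

    def test_null_calibration_and_power(self):
        cfg = SimulationConfig(n_genes=300, ds_gene_fraction=0.1,
                               ds_delta_prop=0.3, dw_gene_fraction=0.0, seed=5)
        ect, gt = simulate_exon_dataset(cfg)
        ds = differential_splicing(exon_proportions(ect), ect.meta,
                                   n_perm=500, seed=3)
        planted = sorted(gt.ds_genes & set(ds.index))
        nulls = sorted(set(ds.index) - gt.ds_genes)
        assert (ds.loc[planted, "fdr"] < 0.05).mean() >= 0.8
        assert (ds.loc[nulls, "fdr"] < 0.05).mean() <= 0.05


class TestDifferentialWiringCosplicing:
    def test_identical_exon_data_zero_changed_edges(self):
        rng = np.random.default_rng(4)
        samples = [f"H{i}" for i in range(8)] + [f"L{i}" for i in range(8)]
        meta = pd.DataFrame({"line": ["HIGH"] * 8 + ["LOW"] * 8,
                             "region": ["X"] * 16},
                            index=pd.Index(samples, name="sample_id"))
        profiles = {}
        for g in range(4):
            shared = rng.dirichlet([1, 1, 1], size=8)
            props = pd.DataFrame(np.vstack([shared, shared]).T,
                                 index=["e0", "e1", "e2"], columns=samples)
            profiles[f"g{g}"] = ExonUsageProfile(
                f"g{g}", props, pd.Series(True, index=samples)
            )
        dwc = differential_wiring_cosplicing(profiles, meta, n_perm=100, seed=2)
        assert (dwc["changed_edge_count"] == 0).all()

    def test_planted_splicing_rewired_pair_flagged(self):
        """Two genes share usage structure in LOW, independent in HIGH."""
        rng = np.random.default_rng(9)
        n = 24
        samples = [f"H{i}" for i in range(n)] + [f"L{i}" for i in range(n)]
        meta = pd.DataFrame({"line": ["HIGH"] * n + ["LOW"] * n,
                             "region": ["X"] * 2 * n},
                            index=pd.Index(samples, name="sample_id"))
        x_low = rng.uniform(0.1, 0.9, size=n)

        def gene(x_states):
            p = np.stack([x_states, 1 - x_states])
            return p

        profiles = {}
        # genes 0 and 1 follow the same state trace in LOW, private in HIGH
        for g in range(6):
            if g < 2:
                x_hi = rng.uniform(0.1, 0.9, size=n)
                states = np.concatenate([x_hi, x_low])
            else:
                states = rng.uniform(0.1, 0.9, size=2 * n)
            props = pd.DataFrame(gene(states), index=["e0", "e1"],
                                 columns=samples)
            profiles[f"g{g}"] = ExonUsageProfile(
                f"g{g}", props, pd.Series(True, index=samples)
            )
        dwc = differential_wiring_cosplicing(profiles, meta, 0.5,
                                             n_perm=400, seed=7)
        assert dwc.loc["g0", "changed_edge_count"] >= 1
        assert dwc.loc["g1", "changed_edge_count"] >= 1
        assert dwc.loc["g0", "fdr"] < 0.05 and dwc.loc["g1", "fdr"] < 0.05
        assert (dwc["p"] >= 1 / 401 - 1e-12).all()
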