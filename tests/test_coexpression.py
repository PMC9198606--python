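"""Network construction, module detection and enrichment oracles."""

import math

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from tmenet import (
    ExpressionMatrix, NetworkParams, build_network, connectivity_stats,
    detect_modules, filter_good_genes_samples, module_eigengenes,
    ora_enrichment, pick_soft_threshold, scale_free_fit_index, select_hubs,
)


def _expr(arr, prefix="g"):
    arr = np.asarray(arr, dtype=float)
    return ExpressionMatrix(
        pd.DataFrame(arr, index=[f"{prefix}{i}" for i in range(arr.shape[0])],
                     columns=[f"s{j}" for j in range(arr.shape[1])]),
        "log2tpm1")


def _planted_blocks(rng, n_blocks=2, block=50, n_noise=0, n_samples=300, cor=0.8):
    rows, truth = [], []
    for b in range(n_blocks):
        factor = rng.standard_normal(n_samples)
        noise_sd = np.sqrt(1 / cor - 1)
        for _ in range(block):
            rows.append(factor + noise_sd * rng.standard_normal(n_samples))
            truth.append(f"block{b}")
    for _ in range(n_noise):
        rows.append(rng.standard_normal(n_samples))
        truth.append("noise")
    return _expr(np.array(rows)), truth


class TestGoodGenesSamples:
    def test_constant_gene_removed(self, rng):
        arr = rng.normal(size=(5, 10))
        arr[2] = 1.0
        out = filter_good_genes_samples(_expr(arr))
        assert "g2" not in out.genes and out.n_genes == 4

    def test_complete_matrix_unchanged(self, rng):
        expr = _expr(rng.normal(size=(6, 12)))
        out = filter_good_genes_samples(expr)
        pd.testing.assert_frame_equal(out.values, expr.values)

    def test_mostly_missing_gene_removed(self, rng):
        arr = rng.normal(size=(5, 10))
        arr[1, :6] = np.nan  # 60% missing
        out = filter_good_genes_samples(_expr(arr))
        assert "g1" not in out.genes


class TestSoftThreshold:
    def test_power_law_degrees_fit_high(self):
        # deterministic discrete power-law sample via inverse CDF
        u = (np.arange(2000) + 0.5) / 2000
        k = np.floor(1.0 * (1 - u) ** (-1.0 / 1.5))
        fit, slope = scale_free_fit_index(k)
        assert fit >= 0.95 and slope < 0

    def test_random_genes_fit_low_at_power_one(self, rng):
        expr = _expr(rng.standard_normal((100, 200)))
        _, table = pick_soft_threshold(expr, candidate_powers=(1,))
        assert table.loc[0, "fit"] < 0.5

    def test_fit_table_reports_every_power(self, rng):
        expr, _ = _planted_blocks(rng, n_noise=40)
        powers = (1, 3, 5, 7)
        beta, table = pick_soft_threshold(expr, candidate_powers=powers)
        assert list(table["power"]) == list(powers)
        assert table["mean_k"].notna().all()
        assert beta in powers

    def test_degenerate_connectivity_raises(self):
        with pytest.raises(ValueError, match="degenerate"):
            scale_free_fit_index(np.full(100, 3.0))


class TestNetwork:
    def test_perfect_correlation_unit_adjacency_and_tom(self):
        x = np.linspace(0, 1, 30)
        a, tom = build_network(_expr(np.vstack([x, 2 * x + 1])), power=6)
        np.testing.assert_allclose(a.to_numpy(), 1.0, atol=1e-12)
        np.testing.assert_allclose(tom.to_numpy(), 1.0, atol=1e-12)

    def test_independent_genes_near_zero(self, rng):
        a, tom = build_network(_expr(rng.standard_normal((2, 5000))), power=6)
        assert a.iloc[0, 1] < 1e-3 and tom.iloc[0, 1] < 0.05

    def test_tom_matches_triple_loop_on_toy(self, rng):
        expr = _expr(rng.standard_normal((5, 40)))
        a_df, tom_df = build_network(expr, power=3)
        a = a_df.to_numpy()
        n = 5
        k = a.sum(axis=1) - 1
        expected = np.eye(n)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
                expected[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
        np.testing.assert_allclose(tom_df.to_numpy(), expected, atol=1e-12)

    def test_adjacency_tom_invariants(self, rng):
        expr, _ = _planted_blocks(rng, block=20, n_noise=10, n_samples=80)
        a, tom = build_network(expr, power=5)
        for m in (a.to_numpy(), tom.to_numpy()):
            np.testing.assert_allclose(m, m.T, atol=1e-12)
            assert m.min() >= 0 and m.max() <= 1 + 1e-12
            np.testing.assert_allclose(np.diag(m), 1.0)


class TestModuleDetection:
    def test_planted_blocks_recovered(self, rng):
        expr, truth = _planted_blocks(rng, n_blocks=2, block=50, cor=0.8)
        _, tom = build_network(expr, power=6)
        modules = detect_modules(tom, expr, NetworkParams(min_module_size=30))
        non_grey = modules[modules != "grey"]
        assert modules.nunique() == 2 and len(non_grey) == 100
        assert adjusted_rand_score(truth, modules.tolist()) >= 0.95

    def test_pure_noise_mostly_grey(self, rng):
        expr = _expr(rng.standard_normal((120, 100)))
        _, tom = build_network(expr, power=6)
        with pytest.warns(UserWarning):
            modules = detect_modules(tom, expr, NetworkParams(min_module_size=30))
        assert (modules == "grey").mean() >= 0.9

    def test_module_sizes_respect_minimum(self, rng):
        expr, _ = _planted_blocks(rng, n_blocks=3, block=40, n_noise=60)
        _, tom = build_network(expr, power=6)
        modules = detect_modules(tom, expr, NetworkParams(min_module_size=30))
        sizes = modules[modules != "grey"].value_counts()
        assert (sizes >= 30).all()


class TestEigengenes:
    def test_identical_genes_give_standardized_profile(self):
        x = np.sin(np.linspace(0, 7, 40))
        expr = _expr(np.vstack([x, x, x]))
        modules = pd.Series(["m1"] * 3, index=expr.genes)
        me = module_eigengenes(expr, modules).loc["m1"].to_numpy()
        z = (x - x.mean()) / x.std()
        np.testing.assert_allclose(me, z / np.linalg.norm(z), atol=1e-10)

    def test_matches_brute_force_pca_on_toy(self, rng):
        expr = _expr(rng.standard_normal((10, 25)))
        modules = pd.Series(["m1"] * 10, index=expr.genes)
        me = module_eigengenes(expr, modules).loc["m1"].to_numpy()
        z = ((expr.values.T - expr.values.mean(axis=1))
             / expr.values.std(axis=1)).to_numpy().T
        evals, evecs = np.linalg.eigh(z.T @ z)  # sample covariance eigenvectors
        pc1 = evecs[:, -1]
        align = np.sign(pc1 @ me)
        np.testing.assert_allclose(me, align * pc1, atol=1e-8)

    def test_sign_convention_positive_mean_kme(self, adjusted_bulk):
        adj, _, truth = adjusted_bulk
        genes = [g for g in truth.module_map if g in adj.genes]
        modules = pd.Series({g: truth.module_map[g] for g in genes})
        mes = module_eigengenes(adj.subset_genes(genes), modules)
        for mod in mes.index:
            sub = adj.values.loc[modules.index[modules == mod]]
            cors = [np.corrcoef(row, mes.loc[mod])[0, 1]
                    for _, row in sub.iterrows()]
            assert np.mean(cors) > 0
            assert np.linalg.norm(mes.loc[mod]) == pytest.approx(1.0)


class TestConnectivity:
    @pytest.fixture()
    def small_net(self, rng):
        expr, truth = _planted_blocks(rng, n_blocks=1, block=6,
                                      n_noise=0, n_samples=60)
        a, tom = build_network(expr, power=4)
        modules = pd.Series(["m1"] * 6, index=expr.genes)
        mes = module_eigengenes(expr, modules)
        return expr, a, modules, mes

    def test_kwithin_equals_hand_sums(self, small_net):
        expr, a, modules, mes = small_net
        table = connectivity_stats(expr, a, modules, mes)
        arr = a.to_numpy()
        for i, g in enumerate(expr.genes):
            hand = arr[i].sum() - arr[i, i]
            assert table.loc[g, "kwithin"] == pytest.approx(hand, abs=1e-12)

    def test_kme_agrees_with_direct_correlation(self, small_net):
        expr, a, modules, mes = small_net
        table = connectivity_stats(expr, a, modules, mes)
        for g in expr.genes:
            direct = np.corrcoef(expr.values.loc[g], mes.loc["m1"])[0, 1]
            assert abs(table.loc[g, "kme"] - direct) < 1e-10

    def test_exactly_one_gene_with_unit_normalized_kwithin(self, small_net):
        expr, a, modules, mes = small_net
        table = connectivity_stats(expr, a, modules, mes)
        assert (table["kwithin_norm"] == 1.0).sum() == 1

    def test_hub_selection_conjunction_and_strictness(self):
        table = pd.DataFrame({
            "module": ["m"] * 3,
            "kme": [0.9, 0.9, 0.5],
            "kwithin": [1, 1, 1],
            "kwithin_norm": [0.9, 0.4, 0.9],
        }, index=["hub", "low_k", "boundary"])
        assert select_hubs(table) == ["hub"]


class TestOra:
    def test_urn_example(self):
        universe = [f"g{i}" for i in range(20)]
        collection = {"S": universe[:5]}
        query = universe[:4] + universe[10:12]  # overlap 4 of query 6
        res = ora_enrichment(query, collection, universe, min_size=1)
        expected = (math.comb(5, 4) * math.comb(15, 2)
                    + math.comb(5, 5) * math.comb(15, 1)) / math.comb(20, 6)
        assert res.loc[0, "p"] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.0140, abs=5e-4)

    def test_query_equal_to_set_is_most_significant(self):
        universe = [f"g{i}" for i in range(40)]
        collection = {"exact": universe[:6], "other": universe[6:12],
                      "partial": universe[3:9]}
        res = ora_enrichment(universe[:6], collection, universe, min_size=1)
        assert res.loc[0, "set"] == "exact"

    def test_zero_overlap_never_significant(self):
        universe = [f"g{i}" for i in range(30)]
        res = ora_enrichment(universe[:5], {"S": universe[20:30]},
                             universe, min_size=1)
        assert res.loc[0, "p"] > 0.5
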