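"""Ligand-receptor edge weights, top connections and bulk scores."""

import numpy as np
import pandas as pd
import pytest

from tmenet import (
    ExpressionMatrix, alluvial_weights, bulk_comm_score, comm_network_integrate,
    demo_junction_genes, demo_lr_pairs, filter_hub_junction_pairs,
    make_annotation, sc_edge_weights, top_connections,
)

from conftest import exp_survival


def _lr(*pairs):
    return pd.DataFrame(pairs, columns=["ligand", "receptor"])


def _sc_toy():
    """2 types x 2 cells each; ligand L in fibroblasts (means 10/0),
    receptor R in tumor cells (means 0/5)."""
    genes = ["L", "R", "X"]
    vals = np.array([
        [10.0, 10.0, 0.0, 0.0],   # L: fibro mean 10, tumor mean 0
        [0.0, 0.0, 5.0, 5.0],     # R: fibro mean 0, tumor mean 5
        [1.0, 1.0, 1.0, 1.0],
    ])
    expr = ExpressionMatrix(pd.DataFrame(vals, index=genes,
                                         columns=["c0", "c1", "c2", "c3"]), "tpm")
    ann = make_annotation(expr.columns,
                          ["fibroblast", "fibroblast", "tumor", "tumor"])
    return expr, ann


class TestFilterPairs:
    def test_hub_junction_receptor_kept(self):
        lr = _lr(("COL1A1", "ITGA2"), ("AAA", "BBB"))
        out = filter_hub_junction_pairs(lr, hub_genes=["ITGA2"],
                                        junction_genes=["ITGA2"])
        assert list(out.itertuples(index=False)) == [("COL1A1", "ITGA2")]

    def test_non_hub_pairs_dropped_with_warning(self):
        lr = _lr(("AAA", "BBB"))
        with pytest.warns(UserWarning):
            out = filter_hub_junction_pairs(lr, ["ITGA2"], ["ITGA2"])
        assert out.empty

    def test_output_subset_and_unique(self):
        lr = demo_lr_pairs()
        out = filter_hub_junction_pairs(lr, ["ITGA2", "FN1"], demo_junction_genes())
        merged = out.merge(lr, how="left", indicator=True)
        assert (merged["_merge"] == "both").all()
        assert not out.duplicated().any()


class TestEdgeWeights:
    def test_hand_arithmetic_single_edge(self):
        expr, ann = _sc_toy()
        edges = sc_edge_weights(expr, ann, _lr(("L", "R")))
        assert len(edges) == 4  # 2x2 ordered type pairs, self-pairs included
        nonzero = edges[edges["weight"] > 0]
        assert len(nonzero) == 1
        row = nonzero.iloc[0]
        assert (row["sender"], row["target"]) == ("fibroblast", "tumor")
        assert row["weight"] == pytest.approx(50.0)

    def test_zero_ligand_annihilates(self):
        expr, ann = _sc_toy()
        edges = sc_edge_weights(expr, ann, _lr(("L", "R")))
        tumor_sender = edges[(edges["sender"] == "tumor")]
        np.testing.assert_allclose(tumor_sender["weight"], 0.0)

    def test_linearity_in_sender_ligand(self):
        expr, ann = _sc_toy()
        e1 = sc_edge_weights(expr, ann, _lr(("L", "R")))
        doubled = expr.copy()
        doubled.values.loc["L", ["c0", "c1"]] *= 2
        e2 = sc_edge_weights(doubled, ann, _lr(("L", "R")))
        fib = e1["sender"] == "fibroblast"
        np.testing.assert_allclose(e2.loc[fib, "weight"], 2 * e1.loc[fib, "weight"])

    def test_permutation_invariant_within_type(self, rng):
        expr, ann = _sc_toy()
        perm = ["c1", "c0", "c3", "c2"]
        e1 = sc_edge_weights(expr, ann, _lr(("L", "R")))
        e2 = sc_edge_weights(expr.subset_columns(perm), ann, _lr(("L", "R")))
        pd.testing.assert_frame_equal(e1, e2)

    def test_missing_gene_skipped_with_warning(self):
        expr, ann = _sc_toy()
        with pytest.warns(UserWarning, match="GHOST"):
            edges = sc_edge_weights(expr, ann, _lr(("GHOST", "R"), ("L", "R")))
        assert set(edges["ligand"]) == {"L"}


class TestTopConnections:
    def test_single_nonzero_edge_wins(self):
        expr, ann = _sc_toy()
        top = top_connections(sc_edge_weights(expr, ann, _lr(("L", "R"))))
        assert len(top) == 1
        assert top.loc[0, ["sender", "target"]].tolist() == ["fibroblast", "tumor"]

    def test_exact_tie_breaks_lexicographically(self):
        edges = pd.DataFrame({
            "sender": ["tumor", "fibroblast"], "ligand": ["L", "L"],
            "receptor": ["R", "R"], "target": ["B", "B"],
            "weight": [5.0, 5.0],
        })
        top = top_connections(edges)
        assert top.loc[0, "sender"] == "fibroblast"

    def test_matches_exhaustive_scan(self, rng):
        expr, ann = _sc_toy()
        noisy = expr.copy()
        noisy.values.iloc[:, :] = rng.uniform(0.1, 10, size=expr.values.shape)
        edges = sc_edge_weights(noisy, ann, _lr(("L", "R"), ("L", "X")))
        top = top_connections(edges)
        for (lig, rec), grp in edges.groupby(["ligand", "receptor"]):
            best = grp.loc[grp["weight"].idxmax()]
            chosen = top[(top["ligand"] == lig) & (top["receptor"] == rec)].iloc[0]
            assert chosen["weight"] == pytest.approx(best["weight"])

    def test_all_zero_edges_reported_as_no_connection(self):
        edges = pd.DataFrame({"sender": ["tumor"], "ligand": ["L"],
                              "receptor": ["R"], "target": ["B"], "weight": [0.0]})
        top = top_connections(edges)
        assert top.loc[0, "no_connection"]


def _bulk(vals, genes):
    return ExpressionMatrix(
        pd.DataFrame(vals, index=genes,
                     columns=[f"s{j}" for j in range(np.asarray(vals).shape[1])]),
        "tpm")


REFS = {"fibroblast": "COL1A2", "tumor": "EPCAM"}


class TestBulkScore:
    def test_identity_ratios_score_one(self):
        expr = _bulk([[4.0], [4.0], [9.0], [9.0]],
                     ["L", "COL1A2", "R", "EPCAM"])
        s = bulk_comm_score(expr, "L", "R", "fibroblast", "tumor", refs=REFS)
        assert s.iloc[0] == pytest.approx(1.0)

    def test_printed_formula_with_zero_pseudocount(self):
        expr = _bulk([[8.0], [2.0], [18.0], [2.0]],
                     ["L", "COL1A2", "R", "EPCAM"])
        s = bulk_comm_score(expr, "L", "R", "fibroblast", "tumor",
                            refs=REFS, pseudocount=0.0)
        assert s.iloc[0] == pytest.approx(6.0)  # sqrt(4 * 9)

    def test_sqrt_c_homogeneity_at_zero_pseudocount(self, rng):
        vals = rng.uniform(1, 50, size=(4, 6))
        genes = ["L", "COL1A2", "R", "EPCAM"]
        base = bulk_comm_score(_bulk(vals, genes), "L", "R",
                               "fibroblast", "tumor", refs=REFS, pseudocount=0.0)
        scaled = vals.copy()
        scaled[0] *= 4.0  # ligand x c
        s2 = bulk_comm_score(_bulk(scaled, genes), "L", "R",
                             "fibroblast", "tumor", refs=REFS, pseudocount=0.0)
        np.testing.assert_allclose(s2, base * 2.0)  # sqrt(4) = 2

    def test_missing_reference_names_cell_type(self):
        expr = _bulk([[1.0], [1.0]], ["L", "R"])
        with pytest.raises(ValueError, match="fibroblast"):
            bulk_comm_score(expr, "L", "R", "fibroblast", "tumor", refs=REFS)


class TestNetworkIntegration:
    @staticmethod
    def _cohort(rng, n=120, beta=0.8):
        u = rng.standard_normal(n)
        genes = ["L", "COL1A2", "R", "EPCAM"]
        vals = np.exp(np.vstack([
            1 + 0.8 * u + 0.1 * rng.standard_normal(n),
            np.full(n, 1.0),
            1 + 0.8 * u + 0.1 * rng.standard_normal(n),
            np.full(n, 1.0),
        ]))
        expr = _bulk(vals, genes)
        surv = exp_survival(rng, u, beta=beta)
        surv.index = expr.columns
        return expr, surv

    def test_single_cohort_hr_passthrough_and_gmean(self, rng):
        top = pd.DataFrame({"sender": ["fibroblast"], "ligand": ["L"],
                            "receptor": ["R"], "target": ["tumor"],
                            "weight": [1.0], "no_connection": [False]})
        c1 = self._cohort(rng)
        one = comm_network_integrate(top, {"a": c1}, refs=REFS)
        assert one.loc[0, "integrated_hr"] == pytest.approx(one.loc[0, "hr_a"])
        c2 = self._cohort(rng)
        two = comm_network_integrate(top, {"a": c1, "b": c2}, refs=REFS)
        expected = np.sqrt(two.loc[0, "hr_a"] * two.loc[0, "hr_b"])
        assert two.loc[0, "integrated_hr"] == pytest.approx(expected)

    def test_hazard_linked_edge_significant(self, rng):
        top = pd.DataFrame({"sender": ["fibroblast"], "ligand": ["L"],
                            "receptor": ["R"], "target": ["tumor"],
                            "weight": [1.0], "no_connection": [False]})
        cohorts = {f"c{i}": self._cohort(rng) for i in range(2)}
        res = comm_network_integrate(top, cohorts, refs=REFS)
        assert res.loc[0, "integrated_hr"] > 1
        assert res.loc[0, "significant_all_cohorts"]

    def test_eventless_cohort_skipped(self, rng):
        top = pd.DataFrame({"sender": ["fibroblast"], "ligand": ["L"],
                            "receptor": ["R"], "target": ["tumor"],
                            "weight": [1.0], "no_connection": [False]})
        expr, surv = self._cohort(rng)
        dead = surv.copy()
        dead["event"] = 0
        with pytest.warns(UserWarning, match="no events"):
            res = comm_network_integrate(
                top, {"ok": (expr, surv), "empty": (expr, dead)}, refs=REFS)
        assert "hr_empty" not in res.columns


class TestAlluvial:
    def test_hand_sums(self):
        expr, ann = _sc_toy()
        top = pd.DataFrame({"sender": ["fibroblast"], "ligand": ["L"],
                            "receptor": ["R"], "target": ["tumor"],
                            "weight": [50.0], "no_connection": [False]})
        mol, cell = alluvial_weights(top, expr, ann)
        lw = mol[mol["molecule"] == "L"]["weight"].iloc[0]
        rw = mol[mol["molecule"] == "R"]["weight"].iloc[0]
        assert lw == pytest.approx(10.0) and rw == pytest.approx(5.0)
        assert cell["fibroblast"] == pytest.approx(10.0)
        assert cell["tumor"] == pytest.approx(5.0)

    def test_cell_weights_are_molecule_sums(self):
        expr, ann = _sc_toy()
        top = pd.DataFrame({
            "sender": ["fibroblast", "fibroblast"], "ligand": ["L", "X"],
            "receptor": ["R", "R"], "target": ["tumor", "tumor"],
            "weight": [50.0, 5.0], "no_connection": [False, False]})
        mol, cell = alluvial_weights(top, expr, ann)
        assert cell["fibroblast"] == pytest.approx(
            mol[mol["cell_type"] == "fibroblast"]["weight"].sum())
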