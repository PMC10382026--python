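"""DE tables, cluster markers, and the predictive-list screening rule."""

import math

import numpy as np
import pandas as pd
import pytest

from chemosig import (
    GeneList,
    GeneSetCollection,
    SimulationConfig,
    de_between_conditions,
    find_cluster_markers,
    screen_gene_lists,
    simulate_bulk_cohort,
    simulate_cell_clusters,
)
from chemosig.exceptions import InputError

from conftest import make_phenotype


class TestDeBetweenConditions:
    def test_identical_groups_yield_no_de(self):
        rng = np.random.default_rng(0)
        half = pd.DataFrame(
            rng.normal(2, 1, (20, 6)), index=[f"g{i}" for i in range(20)], columns=[f"a{i}" for i in range(6)]
        )
        mirror = half.copy()
        mirror.columns = [f"b{i}" for i in range(6)]
        expr = pd.concat([half, mirror], axis=1)
        pheno = make_phenotype(expr.columns, ["R"] * 6 + ["NR"] * 6)
        table = de_between_conditions(expr, pheno)
        assert np.allclose(table["avg_log2FC"], 0.0)
        assert not table["is_de"].any()

    def test_planted_recovery(self):
        cfg = SimulationConfig(
            n_genes=200, n_samples_R=50, n_samples_NR=50, n_signal_genes=20, effect_size_delta=3.0, seed=21
        )
        cohort = simulate_bulk_cohort(cfg)
        table = de_between_conditions(cohort.expression, cohort.phenotype, "NR", "R")
        recovered = set(table.loc[table["is_de"], "gene"]) & set(cohort.truth)
        assert len(recovered) >= 0.9 * len(cohort.truth)

    def test_logfc_matches_hand_calculation(self):
        expr = pd.DataFrame(
            {"s1": [3.0], "s2": [3.0], "s3": [1.0], "s4": [1.0]}, index=["gx"]
        )
        pheno = make_phenotype(expr.columns, ["R", "R", "NR", "NR"])
        table = de_between_conditions(expr, pheno, "R", "NR")
        expected = np.log2(((2**3 - 1) + 1) / ((2**1 - 1) + 1))  # de-logged means, pseudocount 1
        assert table["avg_log2FC"].iloc[0] == pytest.approx(expected, abs=1e-12)
        assert table["direction"].iloc[0] == "up_in_R"

    def test_antisymmetry_under_group_swap(self):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(
            rng.normal(2, 1, (15, 12)), index=[f"g{i}" for i in range(15)], columns=[f"s{i}" for i in range(12)]
        )
        pheno = make_phenotype(expr.columns, ["R"] * 6 + ["NR"] * 6)
        fwd = de_between_conditions(expr, pheno, "R", "NR")
        rev = de_between_conditions(expr, pheno, "NR", "R")
        np.testing.assert_allclose(fwd["avg_log2FC"], -rev["avg_log2FC"], atol=1e-12)

    def test_missing_group_rejected(self):
        expr = pd.DataFrame(np.ones((3, 4)), columns=list("abcd"))
        pheno = make_phenotype(expr.columns, ["R"] * 4)
        with pytest.raises(InputError):
            de_between_conditions(expr, pheno, "R", "NR")


class TestClusterMarkers:
    @pytest.fixture(scope="class")
    def cluster_cohort(self):
        cfg = SimulationConfig(n_genes=100, n_signal_genes=0, effect_size_delta=3.0, seed=31)
        return simulate_cell_clusters(cfg, n_clusters=3, cells_per_cluster=50, markers_per_cluster=10)

    def test_planted_marker_precision(self, cluster_cohort):
        tables = find_cluster_markers(cluster_cohort.expression, cluster_cohort.phenotype)
        for c, table in tables.items():
            markers = set(table.loc[table["is_marker"], "gene"])
            planted = set(cluster_cohort.truth[str(c)])
            assert markers, f"no markers for cluster {c}"
            assert len(markers & planted) / len(markers) >= 0.9

    def test_min_pct_gate_excludes_rare_gene(self, cluster_cohort):
        expr = cluster_cohort.expression.copy()
        # a gene negative everywhere except a few cells of cluster 0: huge
        # shift but detected in <10% of the cluster, so gated out pre-test
        cells0 = cluster_cohort.phenotype.index[cluster_cohort.phenotype["cluster"] == 0]
        rare = pd.Series(-5.0, index=expr.columns)
        rare[cells0[:2]] = 12.0
        expr.loc["rare_gene"] = rare
        tables = find_cluster_markers(expr, cluster_cohort.phenotype)
        assert "rare_gene" not in set(tables[0]["gene"])

    def test_relaxing_min_pct_grows_candidates(self, cluster_cohort):
        strict = find_cluster_markers(cluster_cohort.expression, cluster_cohort.phenotype, min_pct=0.5)
        loose = find_cluster_markers(cluster_cohort.expression, cluster_cohort.phenotype, min_pct=0.0)
        for c in strict:
            assert set(strict[c]["gene"]) <= set(loose[c]["gene"])

    def test_flat_expression_yields_no_markers(self):
        expr = pd.DataFrame(np.ones((10, 12)), index=[f"g{i}" for i in range(10)], columns=[f"c{i}" for i in range(12)])
        pheno = pd.DataFrame({"cluster": [0] * 6 + [1] * 6}, index=expr.columns)
        tables = find_cluster_markers(expr, pheno)
        assert all(len(t) == 0 for t in tables.values())

    def test_tiny_cluster_skipped_with_warning(self, cluster_cohort):
        pheno = cluster_cohort.phenotype.copy()
        pheno.iloc[:2, pheno.columns.get_loc("cluster")] = 99
        with pytest.warns(UserWarning, match="fewer than 3 cells"):
            tables = find_cluster_markers(cluster_cohort.expression, pheno)
        assert 99 not in tables


class TestScreenGeneLists:
    @pytest.fixture(scope="class")
    def screen_setup(self):
        cfg = SimulationConfig(
            n_genes=200, n_samples_R=40, n_samples_NR=40, n_signal_genes=30, effect_size_delta=2.0, seed=41
        )
        cohort = simulate_bulk_cohort(cfg)
        signal = cohort.truth
        noise = [g for g in cohort.expression.index if g not in signal][:20]
        query = GeneList(name="subtype_NR", genes=signal + noise)
        sets = {f"SIGNAL_{i}": signal[5 * i : 5 * i + 5] for i in range(5)}
        sets.update({f"NOISE_{i}": noise[4 * i : 4 * i + 4] for i in range(5)})
        collection = GeneSetCollection(sets=sets, universe=set(cohort.expression.index))
        return cohort, query, collection

    def test_all_sets_pass_rule(self, screen_setup):
        cohort, query, collection = screen_setup
        signal_only = collection.subset([f"SIGNAL_{i}" for i in range(5)])
        res = screen_gene_lists([query], signal_only, cohort.expression, cohort.phenotype)[0]
        assert res.n_significant == len(res.top_sets) == 5
        assert res.is_predictive

    def test_half_rule_boundary(self, screen_setup):
        """Exactly half of the top sets significant => predictive; one
        fewer => not (the 'no less than half of the top 10' rule)."""
        cohort, query, collection = screen_setup
        base = screen_gene_lists([query], collection, cohort.expression, cohort.phenotype)[0]
        assert len(base.top_sets) == 10
        auc_ps = sorted(p for _, _, p in base.top_sets)
        # choose alpha cut points that land exactly 5 and exactly 4
        alpha5 = (auc_ps[4] + auc_ps[5]) / 2
        alpha4 = (auc_ps[3] + auc_ps[4]) / 2
        at5 = screen_gene_lists([query], collection, cohort.expression, cohort.phenotype, auc_alpha=alpha5)[0]
        at4 = screen_gene_lists([query], collection, cohort.expression, cohort.phenotype, auc_alpha=alpha4)[0]
        assert at5.n_significant == 5 and at5.is_predictive
        assert at4.n_significant == 4 and not at4.is_predictive

    def test_signal_sets_dominate_significance(self, screen_setup):
        cohort, query, collection = screen_setup
        res = screen_gene_lists([query], collection, cohort.expression, cohort.phenotype)[0]
        sig_names = {n for n, _, p in res.top_sets if p < 0.05}
        assert {f"SIGNAL_{i}" for i in range(5)} <= sig_names
        assert res.is_predictive == (res.n_significant >= math.ceil(len(res.top_sets) / 2))

    def test_small_sets_excluded_from_evaluation(self, screen_setup):
        cohort, query, collection = screen_setup
        sets = dict(collection.sets)
        sets["TINY"] = ["zz1", "zz2"]  # absent from the cohort entirely
        coll = GeneSetCollection(sets=sets, universe=set(collection.universe) | {"zz1", "zz2"})
        query2 = GeneList(name="q", genes=query.genes + ["zz1", "zz2"])
        res = screen_gene_lists([query2], coll, cohort.expression, cohort.phenotype)[0]
        assert all(name != "TINY" for name, _, _ in res.top_sets)
        assert "TINY" in res.dropped_sets

    def test_rerun_is_deterministic(self, screen_setup):
        cohort, query, collection = screen_setup
        a = screen_gene_lists([query], collection, cohort.expression, cohort.phenotype)[0]
        b = screen_gene_lists([query], collection, cohort.expression, cohort.phenotype)[0]
        assert a.top_sets == b.top_sets and a.n_significant == b.n_significant


def test_gene_list_orderings():
    table = pd.DataFrame(
        {"gene": ["a", "b", "c"], "avg_log2FC": [0.5, -2.0, 1.0], "p_adjusted": [0.5, 0.01, 0.2]}
    )
    by_fc = GeneList.from_de_table(table, "x", "abs_logFC_desc")
    assert by_fc.genes == ["b", "c", "a"]
    by_p = GeneList.from_de_table(table, "x", "p_adjusted_asc")
    assert by_p.genes == ["b", "c", "a"]
    with pytest.raises(InputError):
        GeneList(name="dup", genes=["a", "a"])
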