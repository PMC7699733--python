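from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from evbal import (
    GeneSetCollection,
    SimulationConfig,
    category_regulation,
    cfra_matrix,
    fit_moderated_model,
    generate_cohort,
    hypergeom_enrichment,
    log_transform,
    quantile_normalize,
    ratios_from_groups,
)
from evbal.simulate import generate_gene_sets


def brute_force_upper_tail(N, K, n, k):
    """P(overlap >= k) by enumerating all C(N, n) query draws."""
    universe = list(range(N))
    category = set(range(K))
    hits = sum(
        1 for draw in combinations(universe, n) if len(category & set(draw)) >= k
    )
    return hits / comb(N, n)


class TestHypergeometricEnrichment:
    def test_textbook_value(self):
        sets = GeneSetCollection.from_dict({"A": [f"g{i}" for i in range(5)]})
        uni = [f"g{i}" for i in range(10)]
        res = hypergeom_enrichment([f"g{i}" for i in range(4)], uni, sets)
        assert res.table.loc["A", "p_value"] == pytest.approx(5 / 210)

    def test_query_equals_universe_gives_p_one(self):
        uni = [f"g{i}" for i in range(8)]
        sets = GeneSetCollection.from_dict({"A": uni[:3]})
        res = hypergeom_enrichment(uni, uni, sets)
        assert res.table.loc["A", "p_value"] == pytest.approx(1.0)

    def test_zero_overlap_gives_p_one(self):
        uni = [f"g{i}" for i in range(8)]
        sets = GeneSetCollection.from_dict({"A": uni[:3]})
        res = hypergeom_enrichment(uni[5:], uni, sets)
        assert res.table.loc["A", "k"] == 0
        assert res.table.loc["A", "p_value"] == pytest.approx(1.0)

    @pytest.mark.parametrize("N,K,n", [(8, 3, 4), (10, 5, 4), (12, 6, 5), (15, 4, 7)])
    def test_matches_subset_enumeration(self, N, K, n):
        uni = [f"g{i}" for i in range(N)]
        sets = GeneSetCollection.from_dict({"A": uni[:K]})
        rng = np.random.default_rng(N * 100 + K)
        query = list(rng.choice(uni, size=n, replace=False))
        res = hypergeom_enrichment(query, uni, sets)
        k = res.table.loc["A", "k"]
        assert res.table.loc["A", "p_value"] == pytest.approx(
            brute_force_upper_tail(N, K, n, k), abs=1e-12
        )

    def test_empty_universe_rejected(self):
        sets = GeneSetCollection.from_dict({"A": ["x"]})
        with pytest.raises(ValueError):
            hypergeom_enrichment([], [], sets)


class TestCategoryRegulation:
    def _ratios(self, d):
        return pd.Series(d)

    def test_up_call_with_stars(self):
        # 30 background proteins at ~0, one category clearly shifted
        rng = np.random.default_rng(0)
        background = {f"b{i}": rng.normal(0, 0.05) for i in range(30)}
        members = {"m1": 1.3, "m2": 1.4, "m3": 1.2}
        ratios = self._ratios({**background, **members})
        sets = GeneSetCollection.from_dict({"cat": list(members)})
        res = category_regulation(ratios, sets, query_list=list(members))
        (r,) = res
        assert r.direction == "up"
        assert r.fold_change == pytest.approx(2 ** 1.3, rel=1e-6)
        assert r.stars_regulation in ("**", "***")
        assert r.stars_enrichment in ("*", "**", "***")

    def test_below_twofold_is_unregulated_despite_significance(self):
        rng = np.random.default_rng(1)
        background = {f"b{i}": rng.normal(0, 0.05) for i in range(30)}
        members = {f"m{i}": 0.85 + 0.01 * i for i in range(5)}  # FC ~ 1.8
        ratios = self._ratios({**background, **members})
        sets = GeneSetCollection.from_dict({"cat": list(members)})
        (r,) = category_regulation(ratios, sets, query_list=list(members))
        assert abs(r.fold_change - 2 ** np.mean(list(members.values()))) < 1e-9
        assert r.fold_change < 2.0
        assert r.p_regulation < 0.05 and r.p_enrichment < 0.05
        assert r.direction == "unregulated"

    def test_all_zero_ratios_are_unregulated_with_fc_one(self):
        ratios = self._ratios({f"m{i}": 0.0 for i in range(5)})
        sets = GeneSetCollection.from_dict({"cat": [f"m{i}" for i in range(5)]})
        (r,) = category_regulation(ratios, sets, query_list=list(ratios.index))
        assert r.fold_change == 1.0
        assert r.direction == "unregulated"

    def test_infinite_fc_threshold_yields_no_regulated_categories(self):
        rng = np.random.default_rng(2)
        ratios = self._ratios({f"g{i}": rng.normal(3, 0.1) for i in range(40)})
        sets = GeneSetCollection.from_dict(
            {"a": [f"g{i}" for i in range(10)], "b": [f"g{i}" for i in range(10, 25)]}
        )
        res = category_regulation(
            ratios, sets, query_list=list(ratios.index)[:10], fc_threshold=np.inf
        )
        assert all(r.direction == "unregulated" for r in res)

    def test_invariant_to_member_order_and_duplicate_annotations(self):
        rng = np.random.default_rng(3)
        ratios = self._ratios({f"g{i}": rng.normal(1.5, 0.2) for i in range(20)})
        members = [f"g{i}" for i in range(8)]
        sets_a = GeneSetCollection.from_dict({"cat": members})
        sets_b = GeneSetCollection.from_dict({"cat": members[::-1] + members[:1]})
        q = [f"g{i}" for i in range(10)]
        ra = category_regulation(ratios, sets_a, query_list=q)[0]
        rb = category_regulation(ratios, sets_b, query_list=q)[0]
        assert ra.p_regulation == pytest.approx(rb.p_regulation)
        assert ra.p_enrichment == pytest.approx(rb.p_enrichment)
        assert ra.direction == rb.direction

    def test_single_member_category_excluded(self):
        ratios = self._ratios({"a": 1.0, "b": 2.0, "c": 0.1})
        sets = GeneSetCollection.from_dict({"solo": ["a"], "pair": ["a", "b"]})
        res = category_regulation(ratios, sets, query_list=["a", "b"])
        assert [r.category for r in res] == ["pair"]


class TestCfraMatrix:
    def _mk(self, direction="up", cat="cat"):
        from evbal.cfra import CategoryRegulation

        return CategoryRegulation(
            category=cat,
            n_identified=3,
            n_annotated=10,
            mean_log2_ratio=1.5,
            fold_change=2.8,
            p_regulation=0.004,
            p_enrichment=0.01,
            direction=direction,
            stars_regulation="**",
            stars_enrichment="*",
        )

    def test_single_up_cell(self):
        table = cfra_matrix({"comp": [self._mk()]})
        assert len(table) == 1
        assert table.iloc[0]["direction"] == "up"

    def test_absent_comparison_rendered_unregulated(self):
        table = cfra_matrix({"A": [self._mk()], "B": []})
        b_cell = table[table["comparison"] == "B"].iloc[0]
        assert b_cell["direction"] == "unregulated"
        assert b_cell["n_identified"] == 0

    def test_categories_never_directional_are_dropped(self):
        table = cfra_matrix({"A": [self._mk(direction="unregulated")]})
        assert table.empty

    def test_planted_category_recovered_across_seeds(self):
        hits, null_calls, null_cells = 0, 0, 0
        n_seeds = 30
        for s in range(n_seeds):
            cfg = SimulationConfig(
                seed=s,
                n_genes=600,
                isoforms_per_gene_mean=1.0,
                n_de=40,
                de_log2fc=1.5,
                extra_unique_mean=0.0,
            )
            q, meta, truth = generate_cohort(cfg)
            norm = quantile_normalize(log_transform(q))
            de = fit_moderated_model(norm, meta, covariates=())
            ratios = pd.Series(de.table["log2fc"].values, index=de.table.index)
            sig = list(de.table.index[de.table["p_value"] < 0.05])
            sets = generate_gene_sets(
                list(q.data.index),
                planted=truth["de_up_protein_ids"],
                n_null_sets=5,
                set_size=20,
                seed=s,
            )
            for r in category_regulation(ratios, sets, sig):
                if r.category == "planted_category":
                    hits += r.direction == "up"
                else:
                    null_cells += 1
                    null_calls += r.direction != "unregulated"
        assert hits / n_seeds >= 0.95
        assert null_calls / null_cells <= 0.1
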