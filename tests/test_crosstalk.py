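"""Hypergeometric enrichment and the pathway-crosstalk graph."""

import itertools

import numpy as np
import pytest

from convergenet.crosstalk import (
    build_crosstalk_graph,
    crosstalk_score,
    fisher_enrich,
    functional_groups,
    hypergeom_tail_oracle,
)
from convergenet.model import GeneSet, PathwayCollection

from conftest import geneset


def genes(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:03d}" for i in range(n)]


def collection(*pathway_genes, names=None) -> PathwayCollection:
    names = names or [f"P{i}" for i in range(len(pathway_genes))]
    return PathwayCollection(
        pathways=[GeneSet.from_iterable(n, g) for n, g in zip(names, pathway_genes)]
    )


class TestFisherEnrich:
    def test_zero_hits_give_p_one(self):
        bg = geneset(*genes("B", 50))
        coll = collection(genes("B", 50)[40:])
        res = fisher_enrich(geneset(*genes("B", 50)[:10]), coll, bg)
        assert res.table.loc[0, "p"] == 1.0

    def test_closed_form_count_check(self):
        """N=20, K=10, n=10, k=10: p = 1/C(20,10) = 1/184756."""
        bg = geneset(*genes("B", 20))
        pw = genes("B", 20)[:10]
        res = fisher_enrich(geneset(*pw), collection(pw), bg, min_hits=5)
        assert res.table.loc[0, "p"] == pytest.approx(1 / 184756, rel=1e-12)

    def test_query_equals_pathway_matches_oracle(self):
        bg = geneset(*genes("B", 100))
        pw = genes("B", 100)[:8]
        res = fisher_enrich(geneset(*pw), collection(pw), bg)
        expected = float(hypergeom_tail_oracle(8, 100, 8, 8))
        assert res.table.loc[0, "p"] == pytest.approx(expected, abs=1e-15)

    def test_matches_direct_summation_oracle_on_random_configs(self):
        rng = np.random.default_rng(11)
        universe = genes("B", 200)
        for _ in range(200):
            N = int(rng.integers(20, 200))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            bg = geneset(*universe[:N])
            pw = universe[:K]
            query = geneset(*rng.choice(universe[:N], size=n, replace=False))
            res = fisher_enrich(query, collection(pw), bg, min_hits=0)
            k = res.table.loc[0, "n_hits"]
            assert res.table.loc[0, "p"] == pytest.approx(
                float(hypergeom_tail_oracle(int(k), N, K, n)), abs=1e-12
            )

    def test_significance_needs_both_thresholds(self):
        bg = geneset(*genes("B", 1000))
        pw4, pw6 = genes("B", 1000)[:4], genes("B", 1000)[:6]
        query = geneset(*genes("B", 1000)[:6])
        res = fisher_enrich(query, collection(pw4, pw6), bg, min_hits=5, p_cutoff=0.01)
        by_name = res.table.set_index("pathway")
        assert not by_name.loc["P0", "significant"]  # only 4 hits despite tiny p
        assert by_name.loc["P1", "significant"]

    def test_background_smaller_than_query_is_an_error(self):
        with pytest.raises(ValueError, match="background"):
            fisher_enrich(geneset(*genes("Q", 10)), collection(genes("Q", 3)),
                          geneset(*genes("Q", 5)))

    def test_empty_collection_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            fisher_enrich(geneset("A"), PathwayCollection(pathways=[]), geneset("A", "B"))


class TestCrosstalkScore:
    def test_identical_sets_score_one(self):
        a = geneset("A", "B", "C")
        assert crosstalk_score(a, a) == (1.0, 1.0, 1.0)

    def test_disjoint_sets_score_zero(self):
        assert crosstalk_score(geneset("A"), geneset("B")) == (0.0, 0.0, 0.0)

    def test_hand_counted_example(self):
        jc, oc, score = crosstalk_score(geneset("A", "B", "C"), geneset("B", "C", "D"))
        assert jc == pytest.approx(0.5)
        assert oc == pytest.approx(2 / 3)
        assert score == pytest.approx(7 / 12)

    def test_empty_set_is_an_error(self):
        with pytest.raises(ValueError, match="non-empty"):
            crosstalk_score(GeneSet(name="x", genes=frozenset()), geneset("A"))

    @pytest.mark.parametrize("seed", range(10))
    def test_symmetric_and_jc_bounded_by_oc(self, seed):
        rng = np.random.default_rng(seed)
        pool = genes("G", 20)
        a = geneset(*rng.choice(pool, size=rng.integers(1, 15), replace=False))
        b = geneset(*rng.choice(pool, size=rng.integers(1, 15), replace=False))
        jc, oc, score = crosstalk_score(a, b)
        assert crosstalk_score(b, a) == (jc, oc, score)
        assert 0 <= jc <= oc <= 1
        assert score == pytest.approx((jc + oc) / 2)


def enrich_all(pathways: PathwayCollection, extra_bg: int = 200):
    """Enrichment result in which every pathway is significant with its full
    gene set as hits (query = union of pathway genes, large background)."""
    union = sorted(set().union(*(p.genes for p in pathways)))
    bg = geneset(*(union + genes("X", extra_bg)))
    return fisher_enrich(geneset(*union), pathways, bg, min_hits=1, p_cutoff=0.5)


class TestCrosstalkGraph:
    def test_single_pathway_gives_bare_node(self):
        coll = collection(genes("G", 10))
        res = enrich_all(coll)
        g = build_crosstalk_graph(res, res, top_fraction_a=1.0, top_fraction_b=1.0)
        assert g.graph.number_of_nodes() == 1
        assert g.graph.number_of_edges() == 0
        assert g.groups == []

    def test_two_shared_genes_below_min_shared_gives_no_edge(self):
        pool = genes("G", 20)
        coll = collection(pool[:6], pool[4:10])  # share exactly 2
        res = enrich_all(coll)
        g = build_crosstalk_graph(res, res, min_shared=3,
                                  top_fraction_a=1.0, top_fraction_b=1.0)
        assert g.graph.number_of_edges() == 0

    def test_top_fraction_one_keeps_all_qualifying_pairs(self):
        rng = np.random.default_rng(8)
        pool = genes("G", 40)
        sets = [sorted(rng.choice(pool, size=12, replace=False)) for _ in range(6)]
        coll = collection(*sets)
        res = enrich_all(coll)
        g = build_crosstalk_graph(res, res, min_shared=3,
                                  top_fraction_a=1.0, top_fraction_b=1.0)
        expected = sum(
            1 for a, b in itertools.combinations(range(6), 2)
            if len(set(sets[a]) & set(sets[b])) >= 3
        )
        assert g.graph.number_of_edges() == expected

    def test_filters_are_anti_monotone(self):
        rng = np.random.default_rng(9)
        pool = genes("G", 30)
        sets = [sorted(rng.choice(pool, size=10, replace=False)) for _ in range(8)]
        res = enrich_all(collection(*sets))

        def n_edges(min_shared, frac):
            return build_crosstalk_graph(
                res, res, min_shared=min_shared,
                top_fraction_a=frac, top_fraction_b=frac,
            ).graph.number_of_edges()

        assert n_edges(4, 1.0) <= n_edges(3, 1.0) <= n_edges(2, 1.0)
        assert n_edges(3, 0.2) <= n_edges(3, 0.6) <= n_edges(3, 1.0)

    def test_bad_top_fraction_is_an_error(self):
        res = enrich_all(collection(genes("G", 8)))
        with pytest.raises(ValueError, match="top_fraction"):
            build_crosstalk_graph(res, res, top_fraction_a=0.0, top_fraction_b=1.0)

    def test_membership_both_requires_significance_in_both(self):
        pool = genes("G", 30)
        coll_a = collection(pool[:10], pool[8:18], names=["P0", "P1"])
        coll_b = collection(pool[8:18], pool[16:26], names=["P1", "P2"])
        res_a, res_b = enrich_all(coll_a), enrich_all(coll_b)
        g = build_crosstalk_graph(res_a, res_b, top_fraction_a=1.0, top_fraction_b=1.0)
        memb = {n: g.graph.nodes[n]["membership"] for n in g.graph.nodes}
        assert memb == {"P0": "setA", "P1": "both", "P2": "setB"}


class TestFunctionalGroups:
    def _triangle_sets(self, prefix, pool):
        core = pool[:4]
        return [core + pool[4 + 3 * i: 7 + 3 * i] for i in range(3)]

    def test_two_disjoint_triangles_give_two_groups(self):
        pool_a, pool_b = genes("A", 20), genes("B", 20)
        sets = self._triangle_sets("A", pool_a) + self._triangle_sets("B", pool_b)
        res = enrich_all(collection(*sets))
        g = build_crosstalk_graph(res, res, top_fraction_a=1.0, top_fraction_b=1.0)
        assert len(g.groups) == 2
        assert all(len(grp) == 3 for grp in g.groups)

    def test_fully_connected_pathways_form_one_group(self):
        pool = genes("G", 30)
        sets = [pool[:5] + pool[5 + 4 * i: 9 + 4 * i] for i in range(4)]
        res = enrich_all(collection(*sets))
        g = build_crosstalk_graph(res, res, top_fraction_a=1.0, top_fraction_b=1.0)
        assert len(g.groups) == 1 and len(g.groups[0]) == 4

    def test_groups_table_marks_isolated_nodes_as_group_zero(self):
        pool = genes("G", 40)
        sets = [pool[:8], pool[4:12], pool[30:38]]  # third shares nothing
        res = enrich_all(collection(*sets))
        g = build_crosstalk_graph(res, res, top_fraction_a=1.0, top_fraction_b=1.0)
        table = functional_groups(g)
        assert set(table.loc[table["group"] == 0, "pathway"]) == {"P2"}

    @pytest.mark.parametrize("seed", range(5))
    def test_planted_two_cluster_collection_recovered(self, seed):
        from sklearn.metrics import adjusted_rand_score

        from convergenet.simulate import gen_pathways

        coll, truth = gen_pathways(genes("G", 400), n_pathways=6,
                                   cluster_spec=((3, 4), (3, 4)),
                                   pathway_size=20, rng_seed=seed)
        res = enrich_all(coll)
        g = build_crosstalk_graph(res, res, top_fraction_a=1.0, top_fraction_b=1.0)
        assert len(g.groups) == 2
        predicted = {pw: i for i, grp in enumerate(g.groups) for pw in grp}
        names = sorted(predicted)
        truth_labels = [truth.planted_pathway_clusters[n] for n in names]
        pred_labels = [predicted[n] for n in names]
        assert adjusted_rand_score(truth_labels, pred_labels) == 1.0
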