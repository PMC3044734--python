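"""Self-checks of the synthetic-study generators and their planted truth."""

import numpy as np
import pytest

from convergenet.model import GeneSet
from convergenet.simulate import (
    gen_expression,
    gen_interactome,
    gen_pathways,
    gen_seed_sets,
    default_study,
    validate_truth,
)


class TestInteractome:
    def test_edge_count_tracks_mean_degree(self):
        net = gen_interactome(1000, "scale-free", 10.0, rng_seed=0)
        target = 1000 * 10.0 / 2
        assert abs(net.n_edges - target) <= 0.10 * target
        assert net.n_nodes >= 900

    def test_scale_free_degrees_are_heavy_tailed(self):
        net = gen_interactome(1000, "scale-free", 10.0, rng_seed=1)
        degrees = sorted(d for _, d in net.graph.degree())
        assert degrees[-1] > 10 * np.mean(degrees)  # hubs far above the mean
        assert degrees[0] <= 3                       # peripheral proteins exist

    def test_same_seed_reproduces_graph(self):
        a = gen_interactome(300, "scale-free", 8.0, rng_seed=5)
        b = gen_interactome(300, "scale-free", 8.0, rng_seed=5)
        assert a.edges == b.edges

    def test_erdos_renyi_model(self):
        net = gen_interactome(300, "erdos-renyi", 6.0, rng_seed=2)
        assert net.n_nodes > 250

    @pytest.mark.parametrize("kwargs", [
        dict(n_nodes=5), dict(mean_degree=0.0, model="erdos-renyi"),
        dict(model="small-world"),
    ])
    def test_infeasible_parameters_are_errors(self, kwargs):
        base = dict(n_nodes=100, model="scale-free", mean_degree=6.0, rng_seed=0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            gen_interactome(**base)

    def test_graph_is_connected_and_simple(self):
        net = gen_interactome(500, "scale-free", 10.0, rng_seed=3)
        net.validate()
        import networkx as nx

        assert nx.is_connected(net.graph)


class TestSeedSets:
    def test_overlap_count_exact(self, study):
        assert len(study.seeds_a.genes & study.seeds_b.genes) == 5
        assert study.truth.planted_overlap == study.seeds_a.genes & study.seeds_b.genes

    def test_seed_budgets_respected(self, study):
        assert len(study.seeds_a) == 40
        assert len(study.seeds_b) == 20

    def test_bridges_are_not_seeds(self, study):
        assert not study.truth.planted_bridges & study.seeds_a.genes
        assert not study.truth.planted_bridges & study.seeds_b.genes

    def test_no_bridges_requested_gives_empty_truth(self):
        net = gen_interactome(300, "scale-free", 8.0, rng_seed=4)
        _, _, truth = gen_seed_sets(net, 15, 10, n_bridges=0, n_overlap=3, rng_seed=4)
        assert truth.planted_bridges == set()

    def test_infeasible_budget_is_an_error(self):
        net = gen_interactome(300, "scale-free", 8.0, rng_seed=4)
        with pytest.raises(ValueError, match="budget"):
            gen_seed_sets(net, 10, 5, n_bridges=4, n_overlap=4, rng_seed=0)

    def test_determinism(self):
        net = gen_interactome(400, "scale-free", 10.0, rng_seed=6)
        r1 = gen_seed_sets(net, 20, 12, 3, 4, rng_seed=9)
        r2 = gen_seed_sets(net, 20, 12, 3, 4, rng_seed=9)
        assert r1[0].genes == r2[0].genes and r1[1].genes == r2[1].genes
        assert r1[2].planted_bridges == r2[2].planted_bridges


class TestExpression:
    def test_design_shape(self, study):
        expr = study.expression
        assert expr.n_case == 7 and expr.n_control == 8
        n_genes = len(set(expr.probe_to_gene.values()))
        assert len(expr.values) == pytest.approx(1.1 * n_genes, rel=0.02)

    def test_duplicate_probe_is_dimmer(self, study):
        expr = study.expression
        dups = [p for p in expr.values.index if p.endswith("_PB")]
        assert dups, "expected duplicate probes"
        for p in dups[:20]:
            main = p.replace("_PB", "_PA")
            assert expr.values.loc[main].mean() > expr.values.loc[p].mean()

    def test_planted_shift_visible_in_case_means(self, study):
        expr = study.expression
        case = expr.group_samples("case")
        ctrl = expr.group_samples("control")
        de = sorted(study.truth.planted_de)
        probes = [f"{g}_PA" for g in de]
        diffs = (expr.values.loc[probes, case].mean(axis=1)
                 - expr.values.loc[probes, ctrl].mean(axis=1))
        assert diffs.mean() == pytest.approx(2.0, abs=0.3)

    def test_null_fraction_zero_plants_nothing(self):
        expr, truth = gen_expression([f"G{i}" for i in range(50)], 3, 3,
                                     de_fraction=0.0, effect_sd=2.0, rng_seed=0)
        assert truth.planted_de == {}

    def test_determinism(self):
        a, _ = gen_expression([f"G{i}" for i in range(30)], 4, 4, 0.2, 1.5, rng_seed=3)
        b, _ = gen_expression([f"G{i}" for i in range(30)], 4, 4, 0.2, 1.5, rng_seed=3)
        assert a.values.equals(b.values)

    def test_bad_fraction_is_an_error(self):
        with pytest.raises(ValueError, match="de_fraction"):
            gen_expression(["G1"], 3, 3, de_fraction=1.5, effect_sd=1, rng_seed=0)


class TestPathways:
    POOL = [f"G{i:04d}" for i in range(600)]

    def test_sizes_all_equal_pathway_size(self):
        coll, _ = gen_pathways(self.POOL, 8, ((3, 4), (3, 4)), 15, rng_seed=0)
        assert all(len(p) == 15 for p in coll)

    def test_within_cluster_core_shared(self):
        coll, truth = gen_pathways(self.POOL, 6, ((3, 4), (3, 4)), 20, rng_seed=1)
        for label in ("cluster1", "cluster2"):
            members = [coll[n].genes for n, lab in
                       truth.planted_pathway_clusters.items() if lab == label]
            core = set.intersection(*(set(m) for m in members))
            assert len(core) >= 4

    def test_cross_cluster_sharing_below_min_shared(self):
        coll, truth = gen_pathways(self.POOL, 6, ((3, 4), (3, 4)), 20, rng_seed=2)
        c1 = [coll[n].genes for n, lab in truth.planted_pathway_clusters.items()
              if lab == "cluster1"]
        c2 = [coll[n].genes for n, lab in truth.planted_pathway_clusters.items()
              if lab == "cluster2"]
        for a in c1:
            for b in c2:
                assert len(a & b) < 3

    def test_small_core_with_min_shared_three_gives_no_edges(self):
        from convergenet.crosstalk import build_crosstalk_graph
        from test_crosstalk import enrich_all

        coll, _ = gen_pathways(self.POOL, 4, ((2, 2), (2, 2)), 10, rng_seed=3)
        res = enrich_all(coll)
        g = build_crosstalk_graph(res, res, min_shared=3,
                                  top_fraction_a=1.0, top_fraction_b=1.0)
        assert g.graph.number_of_edges() == 0

    def test_infeasible_pool_is_an_error(self):
        with pytest.raises(ValueError, match="genes"):
            gen_pathways(self.POOL[:50], 10, ((3, 4),), 20, rng_seed=0)

    def test_focus_sets_concentrate_cluster_genes(self):
        focus_a = GeneSet.from_iterable("fa", self.POOL[:40])
        focus_b = GeneSet.from_iterable("fb", self.POOL[40:60])
        coll, truth = gen_pathways(self.POOL, 8, ((3, 4), (3, 4)), 20, rng_seed=4,
                                   focus_sets=[focus_a, focus_b])
        c1 = [n for n, lab in truth.planted_pathway_clusters.items()
              if lab == "cluster1"]
        for name in c1:
            assert len(coll[name].genes & focus_a.genes) >= 5


class TestStudy:
    def test_truth_is_consistent_with_artifacts(self, study):
        validate_truth(study)

    def test_write_dir_round_trips(self, sim_dir, study):
        from convergenet import io as cio

        net = cio.read_interactome(sim_dir["ppi"])
        assert net.edges == study.net.edges
        seeds_a = cio.read_gene_set(sim_dir["seeds_a"])
        assert seeds_a.genes == study.seeds_a.genes
        expr = cio.read_expression(sim_dir["expr"], sim_dir["groups"],
                                   sim_dir["probe_map"])
        assert expr.values.shape == study.expression.values.shape
        coll = cio.read_gmt(sim_dir["gmt"])
        assert coll.names == study.pathways.names

    def test_study_regeneration_is_deterministic(self, study):
        again = default_study(rng_seed=7)
        assert again.net.edges == study.net.edges
        assert again.seeds_a.genes == study.seeds_a.genes
        assert again.expression.values.equals(study.expression.values)
        assert again.truth.planted_bridges == study.truth.planted_bridges
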