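import networkx as nx
import numpy as np
import pytest

from pelnet.cooccurrence import (clr_transform, cohesion, find_hubs,
                                 infer_network, modularity_and_modules,
                                 total_connectivity)
from pelnet.errors import ValidationError
from pelnet.io_formats import AbundanceTable


def _table(values, **kw):
    values = np.asarray(values, dtype=float)
    return AbundanceTable([f"t{i}" for i in range(values.shape[0])],
                          [f"s{j}" for j in range(values.shape[1])],
                          values, **kw)


class TestInferNetwork:
    def test_edge_set_invariant_to_depth_rescaling(self):
        rng = np.random.default_rng(0)
        counts = rng.integers(1, 200, (8, 12)).astype(float)
        scaled = counts * rng.integers(1, 20, 12)
        net1 = infer_network(_table(counts), n_perm=200, seed=1)
        net2 = infer_network(_table(scaled), n_perm=200, seed=1)
        assert set(map(frozenset, net1.edges)) == set(map(frozenset, net2.edges))

    def test_planted_pair_recovered_with_sign(self):
        rng = np.random.default_rng(1)
        hits = 0
        for rep in range(20):
            z = rng.standard_normal((6, 40))
            z[1] = 0.95 * z[0] + 0.3 * rng.standard_normal(40)
            p = np.exp(z)
            t = _table(p / p.sum(axis=0), is_relative=True)
            net = infer_network(t, n_perm=500, seed=rep,
                                prune_order1=False)
            if net.has_edge("t0", "t1") and net["t0"]["t1"]["sign"] == "positive":
                hits += 1
        assert hits >= 18

    def test_chain_pruned_by_order1_partial(self):
        rng = np.random.default_rng(2)
        removed = kept = 0
        for rep in range(20):
            a = rng.standard_normal(60)
            b = 0.9 * a + 0.3 * rng.standard_normal(60)
            c = 0.9 * b + 0.3 * rng.standard_normal(60)
            z = np.vstack([a, b, c, rng.standard_normal((3, 60))])
            p = np.exp(z)
            t = _table(p / p.sum(axis=0), is_relative=True)
            net_pruned = infer_network(t, n_perm=300, seed=rep,
                                       prune_order1=True,
                                       partial_r_threshold=0.2)
            kept += net_pruned.has_edge("t0", "t1")
            removed += not net_pruned.has_edge("t0", "t2")
        assert removed > 10      # indirect A-C edge mostly pruned
        assert kept > 15         # direct A-B edge survives

    def test_too_few_samples_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(ValidationError):
            infer_network(_table(rng.random((4, 4))), n_perm=10, seed=0)


class TestFindHubs:
    def test_star_center_unique_hub(self):
        g = nx.star_graph(5)
        res = find_hubs(g)
        assert res.hubs == [0]
        assert not res.degenerate

    def test_ring_degenerate_fallback(self):
        g = nx.cycle_graph(6)
        res = find_hubs(g)
        assert len(res.hubs) == 1
        assert res.degenerate

    def test_edgeless_network_empty(self):
        g = nx.empty_graph(4)
        res = find_hubs(g)
        assert res.hubs == []


class TestModularity:
    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_disconnected_equal_cliques_closed_form(self, k):
        g = nx.Graph()
        for c in range(k):
            clique = [f"c{c}n{i}" for i in range(5)]
            g.add_edges_from((a, b) for i, a in enumerate(clique)
                             for b in clique[i + 1:])
        q, n_modules, membership = modularity_and_modules(g, seed=0)
        assert q == pytest.approx(1 - 1 / k, abs=1e-9)
        assert n_modules == k

    def test_single_clique_zero(self):
        g = nx.complete_graph(6)
        q, n_modules, _ = modularity_and_modules(g, seed=0)
        assert q == pytest.approx(0.0, abs=1e-9)
        assert n_modules == 1

    def test_deterministic_given_seed(self):
        g = nx.gnm_random_graph(30, 60, seed=7)
        out1 = modularity_and_modules(g, seed=5)
        out2 = modularity_and_modules(g, seed=5)
        assert out1 == out2

    def test_edgeless_flagged(self):
        q, n_modules, membership = modularity_and_modules(
            nx.empty_graph(4), seed=0)
        assert q == 0.0 and n_modules == 4


class TestTotalConnectivity:
    def test_equal_edges_and_nodes(self):
        g = nx.cycle_graph(22)
        assert total_connectivity(g)["edges_per_node"] == pytest.approx(1.0)

    def test_tree_closed_form(self):
        g = nx.random_labeled_tree(15, seed=3)
        assert total_connectivity(g)["edges_per_node"] == pytest.approx(14 / 15)


class TestCohesion:
    def test_independent_taxa_total_cohesion_centered(self):
        rng = np.random.default_rng(4)
        vals = rng.random((12, 30))
        res = cohesion(_table(vals), n_null=150, seed=1)
        total = (res.cohesion_pos + res.cohesion_neg).mean()
        assert abs(total) < 0.05

    def test_pure_negative_structure_flagged_infinite(self):
        # a perfectly anti-correlated pair plus a constant filler taxon
        # (excluded from correlations): the only valid pair is negative,
        # so positive cohesion is exactly zero
        x = np.linspace(0.1, 0.8, 10)
        vals = np.vstack([x, 0.9 - x, np.full(10, 0.1)])
        res = cohesion(_table(vals, is_relative=True), n_null=50, seed=2)
        assert res.np_infinite
        assert res.np_ratio == np.inf

    def test_stronger_negative_coupling_raises_np_ratio(self):
        rng = np.random.default_rng(5)
        wins = 0
        for rep in range(20):
            n = 30
            base = rng.random((6, n)) + 0.2
            neg = base.copy()
            neg[1] = 1.5 - base[0] + rng.normal(0, 0.05, n)   # anti-coupled
            pos = base.copy()
            pos[1] = base[0] + rng.normal(0, 0.05, n)         # co-coupled
            r_neg = cohesion(_table(np.abs(neg)), n_null=60, seed=rep)
            r_pos = cohesion(_table(np.abs(pos)), n_null=60, seed=rep)
            wins += r_neg.np_ratio > r_pos.np_ratio
        assert wins >= 18

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(6)
        vals = rng.random((8, 15))
        r1 = cohesion(_table(vals), n_null=40, seed=9)
        r2 = cohesion(_table(vals), n_null=40, seed=9)
        assert r1.np_ratio == r2.np_ratio
        assert (r1.connectedness_pos == r2.connectedness_pos).all()


def test_clr_is_sample_centered():
    rng = np.random.default_rng(7)
    X = clr_transform(_table(rng.integers(0, 50, (6, 10)).astype(float) + 1))
    np.testing.assert_allclose(X.mean(axis=0), 0.0, atol=1e-12)
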