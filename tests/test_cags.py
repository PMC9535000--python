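import numpy as np
import pandas as pd
import pytest

import oracles
from pelnet.cags import (build_wiggum, cluster_cags, collapse_to_level,
                         kendall_matrix, over_abundance)
from pelnet.errors import ValidationError
from pelnet.io_formats import AbundanceTable, read_network, to_relative, write_network


def _table(values, taxa=None, samples=None, **kw):
    values = np.asarray(values, dtype=float)
    taxa = taxa or [f"t{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return AbundanceTable(taxa, samples, values, **kw)


class TestCollapse:
    TAXONOMY = {"asv1": {"order": "Vibrionales"},
                "asv2": {"order": "Vibrionales"},
                "asv3": {"order": "Flavobacteriales"},
                "asv4": {"order": None, "class": "Gammaproteobacteria"}}

    def test_same_order_summed(self):
        t = _table([[0.1, 0.2], [0.2, 0.1], [0.3, 0.3], [0.4, 0.4]],
                   taxa=["asv1", "asv2", "asv3", "asv4"])
        out = collapse_to_level(t, self.TAXONOMY)
        df = out.df
        np.testing.assert_allclose(df.loc["Vibrionales"], [0.3, 0.3])
        assert "Unassigned-Gammaproteobacteria" in df.index

    def test_column_sums_preserved(self):
        rng = np.random.default_rng(1)
        vals = rng.random((4, 5))
        t = _table(vals, taxa=["asv1", "asv2", "asv3", "asv4"])
        out = collapse_to_level(t, self.TAXONOMY)
        np.testing.assert_allclose(out.values.sum(axis=0),
                                   vals.sum(axis=0), atol=1e-12)

    def test_order_level_table_identity(self):
        t = _table([[1.0, 2], [3.0, 4]], taxa=["Vibrionales", "Bacillales"])
        taxonomy = {x: {"order": x} for x in t.taxon_ids}
        out = collapse_to_level(t, taxonomy)
        np.testing.assert_array_equal(out.df.loc[t.taxon_ids].values, t.values)

    def test_missing_taxonomy_rejected(self):
        t = _table([[1.0, 2], [3.0, 4]], taxa=["known", "unknown"])
        with pytest.raises(ValidationError):
            collapse_to_level(t, {"known": {"order": "X"}})


class TestKendall:
    def test_closed_form_pairs(self):
        t = _table([[1, 2, 3, 4, 5],      # concordant with row 1
                    [2, 4, 6, 8, 10],
                    [5, 4, 3, 2, 1]])     # reversed
        c = kendall_matrix(t)
        assert c.tau[0, 1] == pytest.approx(1.0)
        assert c.tau[0, 2] == pytest.approx(-1.0)

    def test_hand_counted_tau(self):
        t = _table([[1, 2, 3, 4, 5], [2, 1, 4, 3, 5]])
        c = kendall_matrix(t)
        # brute-force count on the same vectors
        assert c.tau[0, 1] == pytest.approx(
            oracles.kendall_tau_pairs([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]))

    def test_matches_bruteforce_on_random_small_inputs(self):
        rng = np.random.default_rng(2)
        for n in (5, 6, 7, 8):
            vals = np.round(rng.random((6, n)) * 5)  # ties likely
            vals[0] += np.arange(n) * 0.01           # avoid constant row
            t = _table(vals)
            c = kendall_matrix(t)
            for i in range(6):
                for j in range(i + 1, 6):
                    expect = oracles.kendall_tau_pairs(vals[i], vals[j])
                    if np.isnan(expect):
                        assert c.undefined[i, j]
                    else:
                        assert c.tau[i, j] == pytest.approx(expect, abs=1e-12)

    def test_constant_taxon_flagged(self):
        t = _table([[1, 1, 1, 1, 1], [1, 2, 3, 4, 5], [2, 1, 3, 5, 4]])
        c = kendall_matrix(t)
        assert c.undefined[0, 1] and c.undefined[0, 2]
        assert not c.undefined[1, 2]


class TestClusterCags:
    def test_identical_profiles_merge_first(self):
        rng = np.random.default_rng(3)
        base = rng.random(10)
        vals = np.vstack([base, base, rng.random(10), rng.random(10)])
        t = to_relative(_table(vals))
        part = cluster_cags(t, k=3)
        assert part.membership.iloc[0] == part.membership.iloc[1]

    def test_k_one_single_group(self):
        rng = np.random.default_rng(4)
        t = to_relative(_table(rng.random((5, 8))))
        part = cluster_cags(t, k=1)
        assert part.membership.nunique() == 1

    def test_k_exceeding_taxa_rejected(self):
        rng = np.random.default_rng(5)
        t = to_relative(_table(rng.random((4, 8))))
        with pytest.raises(ValidationError):
            cluster_cags(t, k=9)

    def test_named_by_most_abundant_member(self):
        vals = np.array([[0.6] * 6, [0.1] * 6, [0.05] * 6, [0.25] * 6])
        vals = vals + np.random.default_rng(6).normal(0, 1e-3, vals.shape)
        vals = np.abs(vals)
        t = to_relative(_table(vals, taxa=["big", "small1", "small2", "mid"]))
        part = cluster_cags(t, k=2)
        assert part.name_of("big") == "big"


class TestOverAbundance:
    def test_single_sector_all_ones(self):
        rng = np.random.default_rng(7)
        t = to_relative(_table(rng.random((4, 6))))
        sectors = pd.Series(["only"] * 6, index=t.sample_ids)
        prof = over_abundance(t, sectors)
        np.testing.assert_allclose(prof.ratios.values, 1.0, atol=1e-12)

    def test_hand_computed_ratios_and_tiers(self):
        # taxon with sector means 0.2 (n=2) and 0.1 (n=2): overall 0.15
        vals = np.array([[0.2, 0.2, 0.1, 0.1],
                         [0.8, 0.8, 0.9, 0.9]])
        t = _table(vals, is_relative=True)
        sectors = pd.Series(["north", "north", "south", "south"],
                            index=t.sample_ids)
        prof = over_abundance(t, sectors)
        assert prof.ratios.loc["north", "t0"] == pytest.approx(4 / 3)
        assert prof.ratios.loc["south", "t0"] == pytest.approx(2 / 3)
        assert prof.tiers.loc["north", "t0"] == "bold"
        assert prof.tiers.loc["south", "t0"] == "hidden"

    def test_weighted_mean_identity(self):
        rng = np.random.default_rng(8)
        t = to_relative(_table(rng.random((6, 9))))
        sectors = pd.Series(rng.choice(["a", "b", "c"], 9, replace=True),
                            index=t.sample_ids)
        while sectors.nunique() < 3:
            sectors = pd.Series(rng.choice(["a", "b", "c"], 9),
                                index=t.sample_ids)
        prof = over_abundance(t, sectors)
        w = prof.sector_weights.values[:, None]
        np.testing.assert_allclose((prof.ratios.values * w).sum(axis=0),
                                   1.0, atol=1e-12)


class TestWiggum:
    def _inputs(self, rng, planted=False):
        n = 30
        vals = rng.random((5, n))
        if planted:
            vals[1] = vals[0] * 2 + rng.normal(0, 1e-3, n)
        t = to_relative(_table(np.abs(vals)))
        corr = kendall_matrix(t)
        part = cluster_cags(t, k=2)
        return t, part, corr

    def test_no_significant_edges_keeps_nodes(self):
        rng = np.random.default_rng(9)
        t, part, corr = self._inputs(rng)
        net = build_wiggum(t, part, corr, edge_q=1e-9)
        assert net.number_of_edges() == 0
        assert set(net.nodes) == set(t.taxon_ids)

    def test_planted_pair_yields_positive_edge(self):
        rng = np.random.default_rng(10)
        t, part, corr = self._inputs(rng, planted=True)
        net = build_wiggum(t, part, corr, edge_q=0.05)
        assert net.has_edge("t0", "t1")
        assert net["t0"]["t1"]["sign"] == "positive"

    def test_attributes_round_trip_through_writer(self, tmp_path):
        rng = np.random.default_rng(11)
        t, part, corr = self._inputs(rng, planted=True)
        net = build_wiggum(t, part, corr)
        path = tmp_path / "net.graphml"
        write_network(net, path)
        back = read_network(path)
        for n in net.nodes:
            assert float(back.nodes[n]["mean_abundance"]) == pytest.approx(
                net.nodes[n]["mean_abundance"])
            assert int(back.nodes[n]["cag"]) == net.nodes[n]["cag"]
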