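import io

import numpy as np
import pandas as pd
import pytest
import skbio
from skbio.stats.distance import DistanceMatrix

import oracles
from pelnet.beta import (axis_environment_screen, mantel, pcoa, permanova,
                         unweighted_unifrac)
from pelnet.errors import ValidationError
from pelnet.io_formats import AbundanceTable
from pelnet.synthetic import random_coalescent_tree


def _tree(newick: str) -> skbio.TreeNode:
    return skbio.TreeNode.read(io.StringIO(newick))


def _table(taxa, samples, values):
    return AbundanceTable(taxa, samples, np.asarray(values, dtype=float))


class TestUnifrac:
    def test_identical_presence_zero(self):
        tree = _tree("((A:1,B:1):1,C:2);")
        t = _table(["A", "B", "C"], ["s1", "s2"], [[1, 2], [1, 1], [0, 0]])
        d = unweighted_unifrac(t, tree)
        assert d["s1", "s2"] == pytest.approx(0.0)

    def test_disjoint_singletons_on_star(self):
        tree = _tree("(A:1,B:1,C:1);")
        t = _table(["A", "B", "C"], ["s1", "s2"], [[1, 0], [0, 1], [0, 0]])
        d = unweighted_unifrac(t, tree)
        assert d["s1", "s2"] == pytest.approx(1.0)

    def test_hand_enumerated_shared_branches(self):
        tree = _tree("((A:1,B:1):1,(C:1,D:1):1);")
        t = _table(["A", "B", "C", "D"], ["s1", "s2"],
                   [[1, 1], [1, 0], [0, 1], [0, 0]])
        # s1={A,B}, s2={A,C}.  Observed branches: A, B, (AB), C, (CD)
        # (D's branch subtends neither community), total length 5;
        # branches unique to one community: B, C, (CD), length 3.
        d = unweighted_unifrac(t, tree)
        assert d["s1", "s2"] == pytest.approx(3 / 5)

    def test_missing_taxon_strict_vs_prune(self):
        tree = _tree("((A:1,B:1):1,C:2);")
        t = _table(["A", "B", "X"], ["s1", "s2"], [[1, 1], [1, 0], [1, 1]])
        with pytest.raises(ValidationError):
            unweighted_unifrac(t, tree)
        d = unweighted_unifrac(t, tree, prune_missing=True)
        assert d.shape == (2, 2)

    def test_agrees_with_bruteforce_oracle(self):
        rng = np.random.default_rng(10)
        for _ in range(30):
            taxa = [f"L{i}" for i in range(16)]
            tree = random_coalescent_tree(taxa, rng)
            pres = rng.random((16, 3)) < 0.5
            pres[0, :] = True
            t = _table(taxa, ["a", "b", "c"], pres.astype(float))
            d = unweighted_unifrac(t, tree)
            for i, j in [(0, 1), (0, 2), (1, 2)]:
                sa = {taxa[k] for k in range(16) if pres[k, i]}
                sb = {taxa[k] for k in range(16) if pres[k, j]}
                expect = oracles.unifrac_bruteforce(tree, sa, sb)
                assert d.data[i, j] == pytest.approx(expect, abs=1e-12)

    def test_agrees_with_skbio(self):
        from skbio.diversity import beta_diversity
        rng = np.random.default_rng(11)
        taxa = [f"L{i}" for i in range(12)]
        tree = random_coalescent_tree(taxa, rng)
        counts = ((rng.random((12, 6)) < 0.5)
                  * rng.integers(1, 9, (12, 6)))
        counts[0] = np.maximum(counts[0], 1)
        t = _table(taxa, [f"s{j}" for j in range(6)], counts)
        mine = unweighted_unifrac(t, tree)
        ref = beta_diversity("unweighted_unifrac", counts.T.astype(int),
                             ids=t.sample_ids, taxa=taxa, tree=tree)
        np.testing.assert_allclose(mine.data, ref.data, atol=1e-12)

    def test_semimetric_properties(self):
        rng = np.random.default_rng(12)
        taxa = [f"L{i}" for i in range(10)]
        tree = random_coalescent_tree(taxa, rng)
        pres = (rng.random((10, 5)) < 0.6).astype(float)
        pres[0] = 1.0
        d = unweighted_unifrac(_table(taxa, list("abcde"), pres), tree)
        assert np.allclose(d.data, d.data.T)
        assert np.allclose(np.diag(d.data), 0.0)
        assert (d.data >= 0).all() and (d.data <= 1).all()


class TestPcoa:
    def test_recovers_planar_configuration(self):
        from scipy.spatial.distance import pdist, squareform
        from scipy.spatial import procrustes
        rng = np.random.default_rng(13)
        pts = rng.random((5, 2))
        d = DistanceMatrix(squareform(pdist(pts)), ids=list("abcde"))
        ordn = pcoa(d)
        coords = ordn.coordinates.values[:, :2]
        _, _, disparity = procrustes(pts, coords)
        assert disparity < 1e-9

    def test_collinear_points_single_axis(self):
        m = np.array([[0.0, 1, 2], [1, 0, 1], [2, 1, 0]])
        ordn = pcoa(DistanceMatrix(m, ids=list("abc")))
        assert len(ordn.eigenvalues) == 1
        assert ordn.proportion_explained[0] == pytest.approx(1.0)

    def test_non_euclidean_negative_eigenvalues_reported(self):
        # triangle-inequality-violating toy matrix
        m = np.array([[0.0, 1, 1, 3.5],
                      [1, 0, 1, 1],
                      [1, 1, 0, 1],
                      [3.5, 1, 1, 0]])
        ordn = pcoa(DistanceMatrix(m, ids=list("abcd")))
        assert ordn.negative_eigenvalues.size > 0
        assert (ordn.eigenvalues > 0).all()

    def test_coordinates_centered(self):
        rng = np.random.default_rng(14)
        from scipy.spatial.distance import pdist, squareform
        d = DistanceMatrix(squareform(pdist(rng.random((8, 3)))),
                           ids=[f"s{i}" for i in range(8)])
        ordn = pcoa(d)
        np.testing.assert_allclose(ordn.coordinates.values.mean(axis=0),
                                   0.0, atol=1e-9)


class TestPermanova:
    def _cloud(self, rng, n, shift=0.0):
        pts = rng.normal(0, 1, (n, 2))
        pts[n // 2:] += shift
        from scipy.spatial.distance import pdist, squareform
        return DistanceMatrix(squareform(pdist(pts)),
                              ids=[f"s{i}" for i in range(n)])

    def test_matches_skbio_statistic(self):
        rng = np.random.default_rng(15)
        d = self._cloud(rng, 12, shift=1.0)
        groups = ["a"] * 6 + ["b"] * 6
        mine = permanova(d, groups, n_perm=99, seed=0)
        from skbio.stats.distance import permanova as sk_perm
        ref = sk_perm(d, grouping=groups, permutations=99)
        assert mine.pseudo_f == pytest.approx(float(ref["test statistic"]))

    def test_two_tight_clusters_floor_p(self):
        rng = np.random.default_rng(16)
        pts = np.vstack([rng.normal(0, 0.01, (10, 2)),
                         rng.normal(10, 0.01, (10, 2))])
        from scipy.spatial.distance import pdist, squareform
        d = DistanceMatrix(squareform(pdist(pts)),
                           ids=[f"s{i}" for i in range(20)])
        res = permanova(d, ["a"] * 10 + ["b"] * 10, n_perm=999, seed=1)
        assert res.pvalue == pytest.approx(0.001)

    def test_exhaustive_enumeration_n6(self):
        rng = np.random.default_rng(17)
        d = self._cloud(rng, 6, shift=1.5)
        codes = np.array([0, 0, 0, 1, 1, 1])
        p_exact = oracles.permanova_exhaustive_p(d.data, codes)
        res = permanova(d, ["a"] * 3 + ["b"] * 3, n_perm=9999, seed=2)
        assert abs(res.pvalue - p_exact) < 0.02

    def test_singleton_group_rejected(self):
        rng = np.random.default_rng(18)
        d = self._cloud(rng, 5)
        with pytest.raises(ValidationError):
            permanova(d, ["a"] * 4 + ["b"], n_perm=9, seed=0)

    def test_power_monotone_in_separation(self):
        rng = np.random.default_rng(19)
        pvals = []
        for shift in (0.0, 1.5, 4.0):
            d = self._cloud(rng, 16, shift=shift)
            pvals.append(permanova(d, ["a"] * 8 + ["b"] * 8,
                                   n_perm=199, seed=3).pvalue)
        assert pvals[0] > pvals[2]
        assert pvals[1] >= pvals[2]


class TestMantel:
    def _rand_dm(self, rng, n, ids):
        m = rng.random((n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        return DistanceMatrix(m, ids=ids)

    def test_self_correlation_one(self):
        rng = np.random.default_rng(20)
        d = self._rand_dm(rng, 8, [f"s{i}" for i in range(8)])
        assert mantel(d, d, n_perm=99, seed=0).r == pytest.approx(1.0)

    def test_spearman_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(21)
        d1 = self._rand_dm(rng, 8, [f"s{i}" for i in range(8)])
        d2 = DistanceMatrix(np.sqrt(d1.data) * 3, ids=d1.ids)
        assert mantel(d1, d2, method="spearman",
                      n_perm=99, seed=0).r == pytest.approx(1.0)

    def test_pearson_equals_direct_triangle_correlation(self):
        rng = np.random.default_rng(22)
        ids = [f"s{i}" for i in range(9)]
        d1, d2 = self._rand_dm(rng, 9, ids), self._rand_dm(rng, 9, ids)
        res = mantel(d1, d2, method="pearson", n_perm=99, seed=0)
        assert res.r == pytest.approx(
            oracles.pearson_upper_triangles(d1.data, d2.data), abs=1e-12)

    def test_agrees_with_skbio_r(self):
        from skbio.stats.distance import mantel as sk_mantel
        rng = np.random.default_rng(23)
        ids = [f"s{i}" for i in range(10)]
        d1, d2 = self._rand_dm(rng, 10, ids), self._rand_dm(rng, 10, ids)
        mine = mantel(d1, d2, method="spearman", n_perm=99, seed=0)
        r_ref, _, _ = sk_mantel(d1, d2, method="spearman", permutations=0)
        assert mine.r == pytest.approx(float(r_ref), abs=1e-12)

    def test_mismatched_ids_rejected(self):
        rng = np.random.default_rng(24)
        d1 = self._rand_dm(rng, 5, list("abcde"))
        d2 = self._rand_dm(rng, 5, list("fghij"))
        with pytest.raises(ValidationError):
            mantel(d1, d2)


class TestEnvironmentScreen:
    def _ordination(self, rng, n=15):
        from scipy.spatial.distance import pdist, squareform
        pts = rng.normal(0, 1, (n, 3))
        d = DistanceMatrix(squareform(pdist(pts)),
                           ids=[f"s{i}" for i in range(n)])
        return pcoa(d)

    def test_copy_of_axis_is_perfectly_correlated(self):
        rng = np.random.default_rng(25)
        ordn = self._ordination(rng)
        covs = pd.DataFrame({"mirror": ordn.coordinates["MDS1"]})
        res = axis_environment_screen(ordn, covs)
        row = res[(res.axis == "MDS1") & (res.covariate == "mirror")].iloc[0]
        assert row.pearson_r == pytest.approx(1.0)
        assert row.r_squared == pytest.approx(1.0)
        assert bool(row.relevant)

    def test_independent_covariate_not_flagged(self):
        rng = np.random.default_rng(26)
        ordn = self._ordination(rng, n=40)
        covs = pd.DataFrame({"noise": rng.normal(0, 1, 40)},
                            index=ordn.coordinates.index)
        res = axis_environment_screen(ordn, covs)
        assert not res.relevant.any()

    def test_constant_covariate_flagged_not_crashed(self):
        rng = np.random.default_rng(27)
        ordn = self._ordination(rng)
        covs = pd.DataFrame({"const": np.ones(15)},
                            index=ordn.coordinates.index)
        res = axis_environment_screen(ordn, covs)
        assert res.undefined.all()
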