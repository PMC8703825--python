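"""Jaccard similarity, neighbor joining, bootstrap and PCA."""

import numpy as np
import pandas as pd
import pytest
from skbio import DistanceMatrix
from skbio.tree import nj as skbio_nj

from tbpkit.cluster import (bootstrap_support, jaccard, nj_tree, pca, root_at,
                            tree_from_matrix, tree_splits)
from tbpkit.matrix import MarkerMatrix
from tbpkit.pipeline import profile_matrix


def _mm(data, clones=None):
    data = np.asarray(data)
    clones = clones or [f"c{i}" for i in range(len(data))]
    cols = [f"R1_{200 + j}" for j in range(data.shape[1])]
    return MarkerMatrix(pd.DataFrame(data, index=clones, columns=cols))


def _random_tree_metric(rng, n):
    """Path metric of a random binary tree with random positive lengths."""
    ids = [f"t{i}" for i in range(n)]
    clusters = [[i] for i in range(n)]
    d = np.zeros((n, n))
    ext = {i: 0.0 for i in range(n)}  # distance from each leaf to cluster root
    while len(clusters) > 1:
        i, j = sorted(rng.choice(len(clusters), size=2, replace=False))
        li, lj = float(rng.uniform(0.1, 2.0)), float(rng.uniform(0.1, 2.0))
        a, b = clusters[i], clusters[j]
        for x in a:
            for y in b:
                d[x, y] = d[y, x] = ext[x] + li + ext[y] + lj
        for x in a:
            ext[x] += li
        for y in b:
            ext[y] += lj
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [a + b]
    return pd.DataFrame(d, index=ids, columns=ids)


class TestJaccard:
    def test_identical_rows_similarity_one(self):
        s = jaccard(_mm([[1, 1, 0], [1, 1, 0]]))
        assert s.df.iloc[0, 1] == 1.0

    def test_disjoint_rows_similarity_zero(self):
        s = jaccard(_mm([[1, 1, 0], [0, 0, 1]]))
        assert s.df.iloc[0, 1] == 0.0

    def test_one_third_overlap(self):
        s = jaccard(_mm([[1, 1, 0], [1, 0, 1]]))
        assert s.df.iloc[0, 1] == pytest.approx(1 / 3)

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(0)
        s = jaccard(_mm(rng.integers(0, 2, size=(8, 20))))
        v = s.values
        assert np.allclose(v, v.T)
        assert np.allclose(np.diag(v), 1.0)
        assert (v >= 0).all() and (v <= 1).all()

    def test_all_zero_row_warns_and_empty_union_is_one(self):
        with pytest.warns(UserWarning, match="all-zero"):
            s = jaccard(_mm([[0, 0], [0, 0], [1, 0]]))
        assert s.df.iloc[0, 1] == 1.0

    def test_permutation_equivariant(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 2, size=(6, 15))
        perm = rng.permutation(6)
        s = jaccard(_mm(x)).values
        sp = jaccard(_mm(x[perm], clones=[f"c{i}" for i in perm])).values
        assert np.allclose(sp, s[np.ix_(perm, perm)])


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = pd.DataFrame([[0, 3, 4], [3, 0, 5], [4, 5, 0]], dtype=float,
                         index=list("ABC"), columns=list("ABC"))
        t = nj_tree(d)
        lengths = {tip.name: tip.length for tip in t.tips()}
        assert lengths["A"] == pytest.approx((3 + 4 - 5) / 2)
        assert lengths["B"] == pytest.approx((3 + 5 - 4) / 2)
        assert lengths["C"] == pytest.approx((4 + 5 - 3) / 2)

    def test_additive_four_taxon_topology_and_paths(self):
        d = pd.DataFrame([[0, 2, 4, 4], [2, 0, 4, 4],
                          [4, 4, 0, 2], [4, 4, 2, 0]], dtype=float,
                         index=list("ABCD"), columns=list("ABCD"))
        t = nj_tree(d)
        assert tree_splits(t) == {frozenset({"C", "D"})}
        paths = t.tip_tip_distances()
        for a in "ABCD":
            for b in "ABCD":
                if a != b:
                    assert paths[a, b] == pytest.approx(d.at[a, b], abs=1e-12)

    @pytest.mark.parametrize("n,seed", [(5, 0), (6, 1), (7, 2), (8, 3)])
    def test_recovers_random_additive_metric(self, n, seed):
        d = _random_tree_metric(np.random.default_rng(seed), n)
        t = nj_tree(d)
        paths = t.tip_tip_distances()
        for a in d.index:
            for b in d.index:
                if a != b:
                    assert paths[a, b] == pytest.approx(d.at[a, b], abs=1e-9)

    def test_matches_reference_nj_topology(self):
        rng = np.random.default_rng(4)
        m = _mm(rng.integers(0, 2, size=(7, 25)))
        dist = jaccard(m).to_distance()
        mine = tree_splits(nj_tree(dist))
        ref = tree_splits(skbio_nj(DistanceMatrix(dist.values,
                                                  list(dist.index))))
        assert mine == ref

    def test_nan_rejected(self):
        d = np.array([[0, np.nan, 1], [np.nan, 0, 1], [1, 1, 0.0]])
        with pytest.raises(ValueError, match="NaN"):
            nj_tree(d)


class TestRooting:
    @pytest.fixture()
    def four_tree(self):
        d = pd.DataFrame([[0, 2, 4, 4], [2, 0, 4, 4],
                          [4, 4, 0, 2], [4, 4, 2, 0]], dtype=float,
                         index=list("ABCD"), columns=list("ABCD"))
        return nj_tree(d)

    def test_outgroup_sister_to_rest(self, four_tree):
        rooted = root_at(four_tree, "C")
        sides = [frozenset({ch.name}) if ch.is_tip()
                 else frozenset(t.name for t in ch.tips())
                 for ch in rooted.children]
        assert frozenset({"C"}) in sides

    def test_preserves_pairwise_path_lengths(self, four_tree):
        before = four_tree.tip_tip_distances()
        after = root_at(four_tree, "A").tip_tip_distances()
        for a in "ABCD":
            for b in "ABCD":
                if a != b:
                    assert after[a, b] == pytest.approx(before[a, b])

    def test_rooting_idempotent_on_splits(self, four_tree):
        once = root_at(four_tree, "C")
        twice = root_at(once, "C")
        assert tree_splits(once) == tree_splits(twice)

    def test_missing_outgroup_errors(self, four_tree):
        with pytest.raises(ValueError, match="not in tree"):
            root_at(four_tree, "Z")


class TestBootstrap:
    def test_species_split_fully_supported(self, four_species_pools):
        from tbpkit.simulate import simulate_clones
        cohort = simulate_clones(four_species_pools[:2], 5, het_prob=0.0,
                                 seed=6)
        m = profile_matrix(cohort.peaks)
        tree = bootstrap_support(m, n_reps=50, seed=7)
        species_side = frozenset(c for c in m.clone_ids if c.startswith("sp2"))
        for node in tree.non_tips():
            side = frozenset(t.name for t in node.tips())
            if side in (species_side,
                        frozenset(m.clone_ids) - species_side):
                assert node.support == 100.0

    def test_single_replicate_supports_are_binary(self):
        rng = np.random.default_rng(8)
        m = _mm(rng.integers(0, 2, size=(6, 30)))
        tree = bootstrap_support(m, n_reps=1, seed=9)
        sup = {n.support for n in tree.non_tips()
               if getattr(n, "support", None) is not None}
        assert sup <= {0.0, 100.0}

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(10)
        m = _mm(rng.integers(0, 2, size=(6, 30)))
        s1 = [n.support for n in bootstrap_support(m, 20, seed=3).non_tips()
              if getattr(n, "support", None) is not None]
        s2 = [n.support for n in bootstrap_support(m, 20, seed=3).non_tips()
              if getattr(n, "support", None) is not None]
        assert s1 == s2

    def test_clone_order_permutation_preserves_split_supports(self):
        rng = np.random.default_rng(11)
        x = rng.integers(0, 2, size=(7, 40))
        names = [f"c{i}" for i in range(7)]
        m1 = _mm(x, clones=names)
        perm = rng.permutation(7)
        m2 = _mm(x[perm], clones=[names[i] for i in perm])

        def support_map(tree):
            out = {}
            tips = sorted(t.name for t in tree.tips())
            full = frozenset(tips)
            for n in tree.non_tips():
                side = frozenset(t.name for t in n.tips())
                if tips[0] in side:
                    side = full - side
                if getattr(n, "support", None) is not None:
                    out[side] = n.support
            return out

        a = support_map(bootstrap_support(m1, 30, seed=12))
        b = support_map(bootstrap_support(m2, 30, seed=12))
        shared = set(a) & set(b)
        assert shared  # same data: the topology should largely agree
        for side in shared:
            assert a[side] == b[side]


class TestPCA:
    def test_two_clones_pc1_explains_everything(self):
        res = pca(_mm([[1, 0, 1], [0, 1, 1]]), k=1)
        assert res.proportions[0] == pytest.approx(1.0)

    def test_constant_column_contributes_nothing(self):
        rng = np.random.default_rng(13)
        base = rng.integers(0, 2, size=(6, 8))
        with_const = np.hstack([base, np.ones((6, 1), dtype=int)])
        a = pca(_mm(base), k=3)
        b = pca(_mm(with_const), k=3)
        assert np.allclose(a.proportions, b.proportions)

    def test_variance_proportions_match_svd_oracle(self):
        rng = np.random.default_rng(14)
        m = _mm(rng.integers(0, 2, size=(10, 25)))
        res = pca(m, k=4)
        xc = m.df.to_numpy(float) - m.df.to_numpy(float).mean(axis=0)
        s = np.linalg.svd(xc, compute_uv=False)
        expect = (s[:4] ** 2) / (s ** 2).sum()
        assert np.allclose(res.proportions, expect, atol=1e-9)

    def test_matches_sklearn(self):
        from sklearn.decomposition import PCA as SkPCA
        rng = np.random.default_rng(15)
        m = _mm(rng.integers(0, 2, size=(9, 20)))
        res = pca(m, k=3)
        sk = SkPCA(n_components=3).fit(m.df.to_numpy(float))
        assert np.allclose(res.proportions, sk.explained_variance_ratio_,
                           atol=1e-9)
        assert np.allclose(np.abs(res.scores.to_numpy()),
                           np.abs(sk.transform(m.df.to_numpy(float))),
                           atol=1e-9)

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            pca(_mm([[1, 0], [0, 1]]), k=2)

    def test_proportions_sum_below_one(self):
        rng = np.random.default_rng(16)
        res = pca(_mm(rng.integers(0, 2, size=(8, 12))), k=3)
        assert (res.proportions >= 0).all()
        assert res.cumulative_proportion() <= 1.0 + 1e-12


class TestSpeciesTopology:
    def test_species_monophyly_and_hybrid_placement(self, reciprocal_cohort):
        m = profile_matrix(reciprocal_cohort.peaks)
        tree = tree_from_matrix(m)
        splits = tree_splits(tree)
        tips = {t.name for t in tree.tips()}
        for sp in ("sp1", "sp2", "sp3", "sp4"):
            clade = frozenset(c for c in tips if c.startswith(f"{sp}_"))
            anchor = sorted(tips)[0]
            side = clade if anchor not in clade else frozenset(tips) - clade
            assert side in splits, f"{sp} is not monophyletic"
        # hybrids (sp1 x sp3) cluster together, apart from both parents
        hyb = frozenset(c for c in tips if c.startswith("hyb_"))
        anchor = sorted(tips)[0]
        side = hyb if anchor not in hyb else frozenset(tips) - hyb
        assert side in splits
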