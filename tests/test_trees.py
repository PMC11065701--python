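"""Similarity dendrograms, cophenetic distances and tree concordance."""

import itertools

import numpy as np
import pandas as pd
import pytest

from bcrnet.trees import (
    LabeledTree,
    cophenetic_correlation,
    cophenetic_matrix,
    permutation_pvalue,
    read_newick,
    similarity_tree,
    to_newick,
)


def ward_d2_oracle(dist):
    """Brute-force Ward-D2 agglomeration (Lance-Williams recurrence).

    Returns the merge list [(members_a, members_b, height), ...] built by
    scanning all active cluster pairs each step.
    """
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}
    d = {(i, j): float(dist[i, j]) for i in range(n) for j in range(i + 1, n)}
    merges = []
    next_id = n

    def get(a, b):
        return d[(min(a, b), max(a, b))]

    while len(clusters) > 1:
        (a, b), h = min(
            ((pair, get(*pair)) for pair in itertools.combinations(sorted(clusters), 2)),
            key=lambda kv: kv[1],
        )
        na, nb = len(clusters[a]), len(clusters[b])
        merged = sorted(clusters[a] + clusters[b])
        merges.append((sorted(clusters[a]), sorted(clusters[b]), h))
        for c in list(clusters):
            if c in (a, b):
                continue
            nc = len(clusters[c])
            val = np.sqrt(
                ((na + nc) * get(a, c) ** 2 + (nb + nc) * get(b, c) ** 2 - nc * h**2)
                / (na + nb + nc)
            )
            d[(min(c, next_id), max(c, next_id))] = val
        del clusters[a], clusters[b]
        clusters[next_id] = merged
        next_id += 1
    return merges


def cophenetic_oracle(linkage, n):
    """Inter-leaf distance = merge height of the lowest common cluster."""
    members = {i: {i} for i in range(n)}
    out = np.zeros((n, n))
    for k, (a, b, h, _) in enumerate(linkage):
        sa, sb = members[int(a)], members[int(b)]
        for i in sa:
            for j in sb:
                out[i, j] = out[j, i] = h
        members[n + k] = sa | sb
    return out


def random_similarity(n, seed):
    rng = np.random.default_rng(seed)
    pts = rng.normal(size=(n, 2))
    d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    j = 1 - d / (d.max() + 0.1)
    np.fill_diagonal(j, 1.0)
    return j


class TestSimilarityTree:
    def test_two_samples_single_merge_at_distance(self):
        j = pd.DataFrame([[1.0, 0.4], [0.4, 1.0]], index=["a", "b"], columns=["a", "b"])
        t = similarity_tree(j)
        assert t.linkage.shape == (1, 4)
        assert t.linkage[0, 2] == pytest.approx(0.6)

    def test_perfect_blocks_separate(self):
        labels = ["a1", "a2", "b1", "b2"]
        j = np.array(
            [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]], dtype=float
        )
        t = similarity_tree(pd.DataFrame(j, index=labels, columns=labels))
        coph = cophenetic_matrix(t)
        assert coph.loc["a1", "a2"] < coph.loc["a1", "b1"]
        assert coph.loc["b1", "b2"] < coph.loc["a2", "b2"]

    def test_non_symmetric_input_fatal(self):
        j = np.array([[1.0, 0.2], [0.5, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            similarity_tree(j)

    @pytest.mark.parametrize("seed", range(8))
    def test_merge_order_matches_ward_d2_oracle(self, seed):
        n = 4 + seed % 3
        j = random_similarity(n, seed)
        t = similarity_tree(j, labels=[str(i) for i in range(n)])
        d = 1 - j
        np.fill_diagonal(d, 0)
        oracle = ward_d2_oracle(d)
        members = {i: [i] for i in range(n)}
        for k, (a, b, h, _) in enumerate(t.linkage):
            ga, gb = sorted(members[int(a)]), sorted(members[int(b)])
            oa, ob, oh = oracle[k]
            assert {tuple(ga), tuple(gb)} == {tuple(oa), tuple(ob)}
            assert h == pytest.approx(oh, rel=1e-9)
            members[n + k] = sorted(ga + gb)


class TestCopheneticMatrix:
    def test_two_leaf_dendrogram_height(self):
        j = pd.DataFrame([[1.0, 0.7], [0.7, 1.0]], index=["x", "y"], columns=["x", "y"])
        t = similarity_tree(j)
        assert cophenetic_matrix(t).loc["x", "y"] == pytest.approx(0.3)

    def test_edge_weighted_path_sums(self):
        t = read_newick("((a:1,b:1):1,c:1);")
        coph = cophenetic_matrix(t)
        assert coph.loc["a", "b"] == pytest.approx(2.0)
        assert coph.loc["a", "c"] == pytest.approx(3.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_dendrogram_cophenetic_is_ultrametric_and_matches_oracle(self, seed):
        n = 6
        t = similarity_tree(random_similarity(n, seed), labels=[str(i) for i in range(n)])
        coph = cophenetic_matrix(t).to_numpy()
        oracle = cophenetic_oracle(t.linkage, n)
        assert np.allclose(coph, oracle)
        for i, j, k in itertools.permutations(range(n), 3):
            assert coph[i, j] <= max(coph[i, k], coph[j, k]) + 1e-9


class TestCopheneticCorrelation:
    def test_tree_vs_itself_is_one(self):
        t = similarity_tree(random_similarity(5, 0), labels=list("abcde"))
        assert cophenetic_correlation(t, t) == pytest.approx(1.0)

    def test_symmetric_in_arguments(self):
        ta = similarity_tree(random_similarity(6, 1), labels=list("abcdef"))
        tb = similarity_tree(random_similarity(6, 2), labels=list("abcdef"))
        assert cophenetic_correlation(ta, tb) == pytest.approx(cophenetic_correlation(tb, ta))

    def test_label_mismatch_fatal(self):
        ta = similarity_tree(random_similarity(4, 1), labels=list("abcd"))
        tb = similarity_tree(random_similarity(4, 2), labels=list("abce"))
        with pytest.raises(ValueError):
            cophenetic_correlation(ta, tb)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_manual_pearson_on_leaf_pairs(self, seed):
        labels = list("abcdef")
        ta = similarity_tree(random_similarity(6, 10 + seed), labels=labels)
        tb = similarity_tree(random_similarity(6, 20 + seed), labels=labels)
        r = cophenetic_correlation(ta, tb)
        ca = cophenetic_matrix(ta).loc[labels, labels].to_numpy()
        cb = cophenetic_matrix(tb).loc[labels, labels].to_numpy()
        xs, ys = [], []
        for i in range(6):
            for j in range(i + 1, 6):
                xs.append(ca[i, j])
                ys.append(cb[i, j])
        xs, ys = np.array(xs), np.array(ys)
        manual = ((xs - xs.mean()) * (ys - ys.mean())).sum() / (
            np.sqrt(((xs - xs.mean()) ** 2).sum()) * np.sqrt(((ys - ys.mean()) ** 2).sum())
        )
        assert r == pytest.approx(manual)


ASYMMETRIC = "((((a:0.7,b:1.3):0.9,c:2.1):0.6,d:3.4):0.5,e:4.9);"


class TestPermutationPvalue:
    def test_identical_asymmetric_trees_minimal_p(self):
        # distinct branch lengths: no nontrivial relabelling reproduces the
        # cophenetic matrix, so with no drawn permutation attaining r = 1 the
        # p-value is exactly 1/(n_perm + 1)
        t = read_newick(ASYMMETRIC)
        r, p = permutation_pvalue(t, t, n_perm=100, seed=0)
        assert r == pytest.approx(1.0)
        assert p == pytest.approx(1 / 101)

    def test_fully_exchangeable_labels_give_p_one(self):
        star = read_newick("(a:1,b:1,c:1,d:1,e:1);")
        t = read_newick(ASYMMETRIC)
        _, p = permutation_pvalue(t, star, n_perm=50, seed=0)
        assert p == 1.0

    def test_p_never_below_add_one_bound(self):
        for seed in range(5):
            ta = similarity_tree(random_similarity(6, seed), labels=list("abcdef"))
            tb = similarity_tree(random_similarity(6, 50 + seed), labels=list("abcdef"))
            _, p = permutation_pvalue(ta, tb, n_perm=20, seed=seed)
            assert p >= 1 / 21

    def test_joint_relabeling_invariance(self):
        labels = list("abcdef")
        ja, jb = random_similarity(6, 3), random_similarity(6, 4)
        ta = similarity_tree(ja, labels=labels)
        tb = similarity_tree(jb, labels=labels)
        perm = [3, 1, 0, 5, 4, 2]
        relab = ["x" + labels[perm[i]] for i in range(6)]
        ta2 = similarity_tree(ja, labels=relab)
        tb2 = similarity_tree(jb, labels=relab)
        assert cophenetic_correlation(ta, tb) == pytest.approx(cophenetic_correlation(ta2, tb2))

        # exhaustive-permutation p is exactly invariant under joint relabeling
        def exhaustive_p(x, y):
            iu = np.triu_indices(6, k=1)
            xa = x[iu]
            r_obs = np.corrcoef(xa, y[iu])[0, 1]
            hits = 0
            count = 0
            for pi in itertools.permutations(range(6)):
                yp = y[np.ix_(pi, pi)][iu]
                count += 1
                if np.corrcoef(xa, yp)[0, 1] >= r_obs - 1e-12:
                    hits += 1
            return hits / count

        ca = cophenetic_matrix(ta).loc[labels, labels].to_numpy()
        cb = cophenetic_matrix(tb).loc[labels, labels].to_numpy()
        order2 = sorted(relab)
        ca2 = cophenetic_matrix(ta2).loc[order2, order2].to_numpy()
        cb2 = cophenetic_matrix(tb2).loc[order2, order2].to_numpy()
        assert exhaustive_p(ca, cb) == pytest.approx(exhaustive_p(ca2, cb2))

    def test_invalid_n_perm_fatal(self):
        t = read_newick(ASYMMETRIC)
        with pytest.raises(ValueError):
            permutation_pvalue(t, t, n_perm=0)


def test_newick_round_trip_preserves_cophenetic():
    t = similarity_tree(random_similarity(5, 8), labels=list("abcde"))
    t2 = read_newick(to_newick(t))
    c1 = cophenetic_matrix(t).loc[list("abcde"), list("abcde")].to_numpy()
    c2 = cophenetic_matrix(t2).loc[list("abcde"), list("abcde")].to_numpy()
    # dendrogram merge heights vs path sums: d_path(a,b) = 2 * height(LCA) ... / 2
    assert np.allclose(c2, c1, atol=1e-6) or np.allclose(c2, 2 * c1, atol=1e-6)
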