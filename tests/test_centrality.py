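"""Lineage graphs: trimming, Hamming MSTs, degrees, and the classifier."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from helpers import make_records

from bcrnet.centrality import (
    build_clone_lineage_graph,
    evaluate_degree_classifier,
    export_clone_network,
    hamming_matrix,
    mst_degree,
    mst_edges,
    select_network_clones,
    trim_alignment,
    write_graphml,
)


class TestSelectNetworkClones:
    def test_boundaries(self):
        summary = pd.DataFrame(
            {
                "clone_id": ["keep", "one_sample", "shallow"],
                "n_samples_observed": [2, 1, 3],
                "n_unique_vdj": [10, 50, 9],
            }
        )
        assert select_network_clones(summary) == ["keep"]


class TestTrimAlignment:
    def test_gap_free_unchanged(self):
        seqs = ["ACGT" * 25] * 5
        trimmed, window = trim_alignment(seqs)
        assert trimmed == seqs
        assert window == (0, 100)

    def test_column_occupancy_rule(self):
        # 100 sequences x 90 columns; column 0 gapped in 10 (occupancy 0.90),
        # column 1 gapped in 4 (occupancy 0.96): exactly one column trimmed
        base = "A" * 90
        seqs = []
        for i in range(100):
            s = list(base)
            if i < 10:
                s[0] = "-"
            if i < 4:
                s[1] = "-"
            seqs.append("".join(s))
        trimmed, window = trim_alignment(seqs, occupancy=0.95, min_len=80)
        assert window == (1, 90)
        assert all(len(s) == 89 for s in trimmed)

    def test_too_short_after_trim_skipped(self):
        # 79 clean columns flanked by fully gapped ends
        seqs = ["-" + "A" * 79 + "-"] * 10
        assert trim_alignment(seqs, min_len=80) is None

    def test_empty_alignment_fatal(self):
        with pytest.raises(ValueError):
            trim_alignment([])


class TestHammingMatrix:
    def test_examples(self):
        mat = hamming_matrix(["ACGT", "ACGA"])
        assert mat[0, 1] == 1
        assert mat[0, 0] == 0

    def test_gap_counts_as_symbol(self):
        mat = hamming_matrix(["AC-T", "ACGT", "AC-A"])
        assert mat[0, 1] == 1  # gap vs base
        assert mat[0, 2] == 1  # gap vs gap is 0; final base differs
        assert mat[1, 2] == 2

    def test_unequal_lengths_fatal(self):
        with pytest.raises(ValueError):
            hamming_matrix(["ACGT", "ACG"])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_positionwise_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seqs = ["".join(rng.choice(list("ACGT-"), size=30)) for _ in range(8)]
        mat = hamming_matrix(seqs)
        for i in range(8):
            for j in range(8):
                assert mat[i, j] == sum(a != b for a, b in zip(seqs[i], seqs[j]))


def prufer_mst_weight(dist):
    """Exhaustive minimum spanning tree weight via Prüfer-sequence enumeration."""
    n = dist.shape[0]
    best = np.inf
    for seq in itertools.product(range(n), repeat=n - 2):
        degree = np.ones(n, dtype=int)
        for v in seq:
            degree[v] += 1
        seq_list = list(seq)
        total = 0.0
        deg = degree.copy()
        ptr = 0
        leaves = sorted(i for i in range(n) if deg[i] == 1)
        import heapq

        heap = leaves[:]
        heapq.heapify(heap)
        for v in seq_list:
            leaf = heapq.heappop(heap)
            total += dist[leaf, v]
            deg[v] -= 1
            if deg[v] == 1:
                heapq.heappush(heap, v)
        u = heapq.heappop(heap)
        w = heapq.heappop(heap)
        total += dist[u, w]
        best = min(best, total)
    return best


class TestMst:
    def test_star_distances_give_hub_degree(self):
        n = 6
        dist = np.full((n, n), 2)
        dist[0, :] = dist[:, 0] = 1
        np.fill_diagonal(dist, 0)
        deg = mst_degree(dist)
        assert deg[0] == n - 1
        assert (deg[1:] == 1).all()

    def test_chain_distances_give_path(self):
        n = 5
        idx = np.arange(n)
        dist = np.abs(idx[:, None] - idx[None, :])
        deg = mst_degree(dist)
        assert deg[0] == deg[-1] == 1
        assert (deg[1:-1] == 2).all()

    def test_single_variant_fatal(self):
        with pytest.raises(ValueError):
            mst_edges(np.zeros((1, 1)))

    def test_edge_count_and_degree_sum(self):
        rng = np.random.default_rng(0)
        for n in (2, 5, 9):
            pts = rng.normal(size=(n, 3))
            dist = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
            edges = mst_edges(dist)
            deg = mst_degree(dist)
            assert len(edges) == n - 1
            assert deg.sum() == 2 * (n - 1)
            assert (deg >= 1).all()

    @pytest.mark.parametrize("seed", range(4))
    def test_total_weight_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = 6
        dist = rng.integers(1, 6, size=(n, n))
        dist = np.triu(dist, 1) + np.triu(dist, 1).T
        total = sum(w for _, _, w in mst_edges(dist))
        assert total == pytest.approx(prufer_mst_weight(dist.astype(float)))

    @pytest.mark.parametrize("seed", range(4))
    def test_agrees_with_networkx_on_unique_weights(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = 40
        pts = rng.normal(size=(n, 4))
        dist = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        g = nx.Graph()
        for i in range(n):
            for j in range(i + 1, n):
                g.add_edge(i, j, weight=dist[i, j])
        ref = nx.minimum_spanning_tree(g)
        deg = mst_degree(dist)
        assert sorted((min(u, v), max(u, v)) for u, v in ref.edges) == sorted(
            (i, j) for i, j, _ in mst_edges(dist)
        )
        assert all(deg[i] == ref.degree[i] for i in range(n))

    def test_integer_ties_broken_deterministically(self):
        dist = np.array([[0, 1, 1, 1], [1, 0, 1, 1], [1, 1, 0, 1], [1, 1, 1, 0]])
        edges = mst_edges(dist)
        # lowest (i, j) pairs first: 0-1, 0-2, 0-3
        assert edges == [(0, 1, 1.0), (0, 2, 1.0), (0, 3, 1.0)]


def clone_df(seqs, sites=None, umis=None, clone_id="cl1"):
    sites = sites or ["lymph_node"] * len(seqs)
    umis = umis or [1] * len(seqs)
    rows = []
    for i, (s, site, u) in enumerate(zip(seqs, sites, umis)):
        rows.append(
            {
                "vdj_nt": s,
                "site": site,
                "sample_id": f"s_{site}",
                "umi_count": u,
                "shm_count": i,
                "timepoint": hash(site) % 3,
            }
        )
    df = make_records(rows)
    df["clone_id"] = clone_id
    return df


BASE = "ACGT" * 25


def mutate(seq, *positions):
    s = list(seq)
    for p in positions:
        s[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[s[p]]
    return "".join(s)


class TestCloneLineageGraph:
    def test_identical_sequences_grouped_before_mst(self):
        seqs = [BASE, BASE, mutate(BASE, 3), mutate(BASE, 3, 7)]
        df = clone_df(seqs, sites=["lymph_node", "liver", "liver", "liver"])
        totals = df.groupby("sample_id")["umi_count"].sum()
        graph = build_clone_lineage_graph(df, totals)
        assert len(graph.variants) == 3
        assert graph.degrees.sum() == 2 * (3 - 1)

    def test_n_containing_records_excluded(self):
        seqs = [BASE, mutate(BASE, 3), "N" + BASE[1:]]
        df = clone_df(seqs)
        totals = df.groupby("sample_id")["umi_count"].sum()
        graph = build_clone_lineage_graph(df, totals)
        assert len(graph.variants) == 2

    def test_occupancy_annotation(self):
        seqs = [BASE, BASE, mutate(BASE, 5)]
        df = clone_df(seqs, sites=["lymph_node", "liver", "liver"])
        totals = df.groupby("sample_id")["umi_count"].sum()
        graph = build_clone_lineage_graph(df, totals)
        by_seq = dict(zip(graph.variants, graph.n_sites))
        assert by_seq[BASE] == 2
        assert by_seq[mutate(BASE, 5)] == 1

    def test_single_variant_degenerate(self):
        df = clone_df([BASE, BASE])
        totals = df.groupby("sample_id")["umi_count"].sum()
        graph = build_clone_lineage_graph(df, totals)
        assert graph.degenerate

    def test_degrees_invariant_under_row_order(self):
        rng = np.random.default_rng(1)
        seqs = [BASE] + [mutate(BASE, int(p)) for p in rng.choice(100, 6, replace=False)]
        df = clone_df(seqs)
        totals = df.groupby("sample_id")["umi_count"].sum()
        g1 = build_clone_lineage_graph(df, totals)
        g2 = build_clone_lineage_graph(df.sample(frac=1.0, random_state=5), totals)
        assert dict(zip(g1.variants, g1.degrees)) == dict(zip(g2.variants, g2.degrees))

    def test_export_round_trip_preserves_degrees(self, tmp_path):
        seqs = [BASE, mutate(BASE, 3), mutate(BASE, 3, 9)]
        df = clone_df(seqs)
        totals = df.groupby("sample_id")["umi_count"].sum()
        graph = build_clone_lineage_graph(df, totals)
        g = export_clone_network(graph)
        assert g.number_of_edges() == 2
        path = tmp_path / "clone.graphml"
        write_graphml(graph, path)
        back = nx.read_graphml(path)
        assert {n: d for n, d in back.degree} == {n: d for n, d in g.degree}
        for node in g.nodes:
            assert back.nodes[node]["degree"] == g.nodes[node]["degree"]


class TestDegreeClassifier:
    def test_hand_computed_confusion_table(self):
        degrees = [2] * 8 + [1] * 2 + [2] * 5 + [1] * 85
        labels = [True] * 10 + [False] * 90
        out = evaluate_degree_classifier(degrees, labels, cutoffs=(1,))
        row = out.iloc[0]
        assert row["sensitivity"] == pytest.approx(0.8)
        assert row["specificity"] == pytest.approx(85 / 90)
        assert row["accuracy"] == pytest.approx(0.93)

    def test_cutoff_zero_predicts_all_positive(self):
        out = evaluate_degree_classifier([1, 2, 3], [True, False, True], cutoffs=(0,))
        assert out["sensitivity"].iloc[0] == 1.0

    def test_single_class_labels_reported_missing(self):
        out = evaluate_degree_classifier([1, 2], [True, True], cutoffs=(1,))
        assert np.isnan(out["specificity"].iloc[0])

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(2)
        degrees = rng.integers(1, 15, size=300)
        labels = rng.random(300) < 0.3
        out = evaluate_degree_classifier(degrees, labels, cutoffs=(0, 1, 2, 5, 10))
        assert (np.diff(out["sensitivity"]) <= 1e-12).all()
        assert (np.diff(out["specificity"]) >= -1e-12).all()


def test_planted_hubs_have_higher_degree_than_leaves(assigned_sim):
    """Cross-site hub variants planted by the generator sit deeper in the MST."""
    from bcrnet.centrality import centrality_analysis

    cfg, rep, truth, df = assigned_sim
    variants, _ = centrality_analysis(df)
    multi = variants[variants["n_sites"] >= 2]["degree"]
    single = variants[variants["n_sites"] == 1]["degree"]
    assert np.median(multi) > np.median(single)
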