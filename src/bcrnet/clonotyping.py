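"""Clone assignment from sequence networks and CDR3 identity clustering.

A clone is a group of clonally related receptor sequences: identical CDR3
regions and V-gene use, or sequences differing by single point mutations.
Two clustering rules are combined per participant and chain:

1. the sequence network — vertices are unique full-VDJ nucleotide sequences,
   edges join vertices that differ by exactly one non-indel substitution
   (identical sequences are merged implicitly, Hamming 0);
2. single-linkage clustering of equal-length CDR3s with the same gene-level
   V call at an identity threshold (default 0.95).

Clones are the connected components of the union of the two rules; clone ids
are deterministic (lexicographically smallest member id).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from ._seq import UnionFind, pairwise_hamming


@dataclass
class CloneCluster:
    """A set of clonally related records with per-sample abundance."""

    clone_id: str
    chain: str
    v_call: str
    member_index: list
    sample_umi: dict
    sample_unique_vdj: dict

    @property
    def n_samples_observed(self) -> int:
        return len(self.sample_umi)

    @property
    def total_umi(self) -> int:
        return int(sum(self.sample_umi.values()))

    @property
    def n_unique_vdj(self) -> int:
        # distinct rearrangements across all samples of the participant
        return int(sum(self.sample_unique_vdj.values()))


def build_sequence_network(records, group_by_v: bool = True) -> nx.Graph:
    """Build the unique-sequence network (Hamming-1 substitution edges).

    ``records`` may be a DataFrame with ``vdj_nt``/``umi_count`` columns or a
    plain iterable of sequences. Vertices are unique sequences weighted by
    summed UMI count; an edge joins two vertices iff they have equal length
    and Hamming distance exactly 1. Node attribute ``component`` labels the
    connected components.

    Sequences with different gene-level V calls cannot differ by a single
    substitution, so when V calls are available the pairwise scan is
    restricted to records sharing one (``group_by_v=True``).
    """
    if isinstance(records, pd.DataFrame):
        df = records
        seq_umi = df.groupby("vdj_nt")["umi_count"].sum()
        if group_by_v and "v_call" in df.columns:
            groups = [g["vdj_nt"].unique() for _, g in df.groupby("v_call")]
        else:
            groups = [df["vdj_nt"].unique()]
    else:
        seqs = list(records)
        seq_umi = pd.Series(seqs).value_counts()
        groups = [seq_umi.index.to_numpy()]

    graph = nx.Graph()
    for seq, umi in seq_umi.items():
        graph.add_node(seq, umi=int(umi))

    for group in groups:
        by_len: dict[int, list[str]] = {}
        for s in group:
            by_len.setdefault(len(s), []).append(s)
        for seqs in by_len.values():
            if len(seqs) < 2:
                continue
            dist = pairwise_hamming(seqs)
            for i, j in zip(*np.nonzero(np.triu(dist == 1, k=1))):
                graph.add_edge(seqs[i], seqs[j], weight=1)

    for label, comp in enumerate(nx.connected_components(graph)):
        for node in comp:
            graph.nodes[node]["component"] = label
    return graph


def _member_id(row) -> str:
    return f"{row.sample_id}:{row.sequence_id}"


def assign_clones(
    df: pd.DataFrame,
    identity_threshold: float = 0.95,
    on: str = "cdr3",
) -> pd.DataFrame:
    """Assign every record of one participant and chain to exactly one clone.

    Single-linkage clusters over record pairs with the same gene-level V call
    and equal CDR3 length at CDR3 amino-acid identity >= ``identity_threshold``
    (``on='vdj'`` applies the threshold to the full VDJ nucleotide sequence
    instead), unioned with the connected components of the Hamming-1
    full-VDJ sequence network. Returns a copy of ``df`` with a ``clone_id``
    column. The assignment is a partition, and raising the threshold can only
    split clones, never merge them.
    """
    if not (0 < identity_threshold <= 1):
        raise ValueError(f"identity_threshold must be in (0, 1], got {identity_threshold}")
    if on not in ("cdr3", "vdj"):
        raise ValueError(f"on must be 'cdr3' or 'vdj', got {on!r}")
    if df.empty:
        out = df.copy()
        out["clone_id"] = pd.Series(dtype=str)
        return out
    if df["participant_id"].nunique() > 1:
        raise ValueError("assign_clones operates on a single participant")
    if df["chain"].nunique() > 1:
        raise ValueError("assign_clones operates on a single chain")

    df = df.reset_index(drop=True)
    uf = UnionFind(len(df))
    idx = np.arange(len(df))

    # stage 1: identity-threshold single linkage on equal-length CDR3s (or VDJs)
    col = "cdr3_aa" if on == "cdr3" else "vdj_nt"
    key = df[col]
    for (_, _), g in df.groupby([df["v_call"], key.str.len()], sort=False):
        members = idx[g.index]
        seqs = key[g.index]
        uniq, inv = np.unique(seqs.to_numpy(), return_inverse=True)
        first = {}
        for member, u in zip(members, inv):
            if u in first:
                uf.union(first[u], member)
            else:
                first[u] = member
        if len(uniq) > 1 and len(uniq[0]) > 0:
            length = len(uniq[0])
            max_mismatch = length * (1.0 - identity_threshold) + 1e-9
            dist = pairwise_hamming(list(uniq))
            for i, j in zip(*np.nonzero(np.triu(dist <= max_mismatch, k=1))):
                uf.union(first[i], first[j])

    # stage 2: Hamming-1 full-VDJ network components (and identical sequences)
    for (_, _), g in df.groupby([df["v_call"], df["vdj_nt"].str.len()], sort=False):
        members = idx[g.index]
        uniq, inv = np.unique(g["vdj_nt"].to_numpy(), return_inverse=True)
        first = {}
        for member, u in zip(members, inv):
            if u in first:
                uf.union(first[u], member)
            else:
                first[u] = member
        if len(uniq) > 1:
            dist = pairwise_hamming(list(uniq))
            for i, j in zip(*np.nonzero(np.triu(dist == 1, k=1))):
                uf.union(first[i], first[j])

    roots = uf.labels()
    member_ids = np.array([_member_id(r) for r in df.itertuples(index=False)])
    clone_names = {}
    for root in np.unique(roots):
        clone_names[root] = "clone_" + min(member_ids[roots == root])
    out = df.copy()
    out["clone_id"] = [clone_names[r] for r in roots]
    return out


def clone_clusters(df: pd.DataFrame) -> dict[str, CloneCluster]:
    """Materialize :class:`CloneCluster` objects from a clone-assigned table."""
    clusters = {}
    for clone_id, g in df.groupby("clone_id", sort=True):
        clusters[clone_id] = CloneCluster(
            clone_id=clone_id,
            chain=g["chain"].iloc[0],
            v_call=g["v_call"].mode().iloc[0],
            member_index=list(g.index),
            sample_umi={s: int(u) for s, u in g.groupby("sample_id")["umi_count"].sum().items()},
            sample_unique_vdj={
                s: int(u) for s, u in g.groupby("sample_id")["vdj_nt"].nunique().items()
            },
        )
    return clusters


def clone_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Per-clone summary: samples observed, UMI totals and unique VDJ counts."""
    agg = df.groupby("clone_id").agg(
        chain=("chain", "first"),
        n_samples_observed=("sample_id", "nunique"),
        total_umi=("umi_count", "sum"),
        n_unique_vdj=("vdj_nt", "nunique"),
        n_records=("sequence_id", "size"),
    )
    return agg.reset_index()


def clone_sample_umis(df: pd.DataFrame) -> pd.DataFrame:
    """Pivot clone x sample matrix of summed UMI counts (absent = 0)."""
    return (
        df.pivot_table(index="clone_id", columns="sample_id", values="umi_count", aggfunc="sum", fill_value=0)
        .astype(int)
    )


def clone_sample_unique_vdjs(df: pd.DataFrame) -> pd.DataFrame:
    """Pivot clone x sample matrix of unique VDJ sequence counts."""
    return (
        df.groupby(["clone_id", "sample_id"])["vdj_nt"].nunique().unstack(fill_value=0).astype(int)
    )


def membership_table(df: pd.DataFrame) -> pd.DataFrame:
    """Long-format clone membership (sequence_id, sample_id, clone_id)."""
    return df[["sequence_id", "sample_id", "clone_id"]].copy()
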