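"""Clone lineage graphs and degree-centrality prediction of immunosurveillance.

The headline analysis. For every clone seen in at least two samples with at
least ten unique BCR sequences:

1. the clone's aligned sequences are end-trimmed until the terminal columns
   reach 95% non-gap occupancy (clones shorter than 80 nt after trimming are
   skipped);
2. identical trimmed sequences are grouped into one variant, aggregating
   per-sample abundance (UMI share of the sample);
3. a pairwise Hamming distance matrix over the variants feeds a minimum
   spanning tree (deterministic Kruskal, ties broken by the lowest (i, j)
   index pair), and each variant's degree centrality is its number of
   incident MST edges — degree 1 means the variant left no detected progeny.

High-degree variants are the clone's diversification hubs; classifying a
variant as immunosurveilling (observed in >= 2 sites) or temporally
persistent (>= 2 timepoints) when its degree exceeds a cutoff (>1, >2, >10)
gives the sensitivity / specificity / accuracy profiles.

Sequences containing N are excluded from this analysis (their Hamming
distance is undefined).
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from ._seq import pairwise_hamming

logger = logging.getLogger("bcrnet")

DEFAULT_CUTOFFS = (1, 2, 10)
GAP = "-"


def select_network_clones(
    summary: pd.DataFrame,
    min_samples: int = 2,
    min_unique_seqs: int = 10,
) -> list[str]:
    """Clones retained for network analysis: >= 2 samples and >= 10 unique BCRs.

    ``summary`` is the per-clone table from :func:`bcrnet.clonotyping.clone_summary`.
    """
    keep = (summary["n_samples_observed"] >= min_samples) & (
        summary["n_unique_vdj"] >= min_unique_seqs
    )
    return summary.loc[keep, "clone_id"].tolist()


def trim_alignment(msa, occupancy: float = 0.95, min_len: int = 80):
    """End-trim an alignment until terminal columns reach the occupancy target.

    Leading and trailing columns are removed inward until the first and last
    remaining columns each have a non-gap fraction >= ``occupancy``. Returns
    ``(trimmed_sequences, (start, stop))`` or ``None`` if fewer than
    ``min_len`` columns survive (the clone is skipped).
    """
    seqs = list(msa)
    if not seqs:
        raise ValueError("empty alignment")
    mat = np.array([list(s) for s in seqs])
    occ = (mat != GAP).mean(axis=0)
    start, stop = 0, mat.shape[1]
    while start < stop and occ[start] < occupancy:
        start += 1
    while stop > start and occ[stop - 1] < occupancy:
        stop -= 1
    if stop - start < min_len:
        return None
    return ["".join(row) for row in mat[:, start:stop]], (start, stop)


def hamming_matrix(seqs) -> np.ndarray:
    """Pairwise Hamming distances over equal-length (trimmed) sequences.

    Gaps count as ordinary symbols: gap vs base = 1, gap vs gap = 0.
    Raises on unequal lengths.
    """
    return pairwise_hamming(list(seqs))


def mst_edges(dist: np.ndarray) -> list[tuple[int, int, float]]:
    """Minimum spanning tree by Kruskal with deterministic tie-breaking.

    Edges are processed in (weight, i, j) order, so among equal-weight
    candidates the lowest (i, j) index pair wins. Returns (i, j, weight)
    triples, i < j; n - 1 edges for n >= 2 nodes.
    """
    dist = np.asarray(dist)
    n = dist.shape[0]
    if n < 2:
        raise ValueError("MST undefined for fewer than 2 variants")
    iu, ju = np.triu_indices(n, k=1)
    w = dist[iu, ju]
    order = np.lexsort((ju, iu, w))
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    edges = []
    for k in order:
        i, j = int(iu[k]), int(ju[k])
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)
            edges.append((i, j, float(w[k])))
            if len(edges) == n - 1:
                break
    return edges


def mst_degree(dist: np.ndarray) -> np.ndarray:
    """Per-variant degree centrality in the Hamming MST (degree 1 = no progeny)."""
    n = np.asarray(dist).shape[0]
    deg = np.zeros(n, dtype=int)
    for i, j, _ in mst_edges(dist):
        deg[i] += 1
        deg[j] += 1
    return deg


@dataclass
class CloneLineageGraph:
    """Per-clone trimmed unique-variant set with Hamming MST and node degrees."""

    clone_id: str
    variants: list  # trimmed sequences, one per variant
    variant_ids: list
    abundance: pd.DataFrame  # variant x sample UMI share of sample
    distances: np.ndarray
    edges: list
    degrees: np.ndarray
    n_sites: np.ndarray
    n_timepoints: np.ndarray
    frequency: np.ndarray  # summed UMI share across samples
    mean_shm: np.ndarray
    skipped: bool = False
    degenerate: bool = False
    trim_window: tuple | None = None


def align_clone_members(seqs: list) -> list:
    """Align a clone's member sequences.

    Clone members are near-identical substitution-related sequences; if they
    already share one length they are treated as aligned. Mixed lengths are
    aligned with mafft when available (recorded in the log), otherwise the
    clone cannot be analyzed.
    """
    if len({len(s) for s in seqs}) == 1:
        return list(seqs)
    if shutil.which("mafft") is None:
        raise RuntimeError("unequal-length clone members and mafft not available")
    with tempfile.NamedTemporaryFile("w", suffix=".fa", delete=False) as fh:
        for i, s in enumerate(seqs):
            fh.write(f">{i}\n{s}\n")
        path = fh.name
    out = subprocess.run(
        ["mafft", "--auto", "--quiet", path], capture_output=True, text=True, check=True
    ).stdout
    logger.info("aligned %d clone members with mafft", len(seqs))
    aligned = {}
    name = None
    for line in out.splitlines():
        if line.startswith(">"):
            name = int(line[1:])
            aligned[name] = []
        elif name is not None:
            aligned[name].append(line.strip())
    return ["".join(aligned[i]).upper() for i in range(len(seqs))]


def build_clone_lineage_graph(
    clone_df: pd.DataFrame,
    sample_umi_totals: pd.Series,
    occupancy: float = 0.95,
    min_len: int = 80,
) -> CloneLineageGraph | None:
    """Trim, group and MST a single clone's records into a lineage graph.

    ``clone_df`` holds the clone's records (columns vdj_nt, sample_id, site,
    timepoint, umi_count, shm_count); ``sample_umi_totals`` gives each
    sample's total UMI count for the abundance shares. Returns ``None`` for
    a skipped clone (trimmed below ``min_len``); a single-variant clone is
    returned with ``degenerate=True`` and no degrees.
    """
    clone_id = str(clone_df["clone_id"].iloc[0]) if "clone_id" in clone_df else ""
    clean = clone_df[~clone_df["vdj_nt"].str.contains("N")]
    if clean.empty:
        return None
    aligned = align_clone_members(clean["vdj_nt"].tolist())
    trimmed = trim_alignment(aligned, occupancy=occupancy, min_len=min_len)
    if trimmed is None:
        logger.info("clone %s skipped: trimmed length < %d", clone_id, min_len)
        return None
    trimmed_seqs, window = trimmed

    work = clean.copy()
    work["_variant_seq"] = trimmed_seqs
    variant_seqs = sorted(work["_variant_seq"].unique())
    var_index = {s: i for i, s in enumerate(variant_seqs)}
    work["_variant"] = work["_variant_seq"].map(var_index)
    n = len(variant_seqs)

    umi = work.pivot_table(
        index="_variant", columns="sample_id", values="umi_count", aggfunc="sum", fill_value=0
    ).reindex(range(n), fill_value=0)
    share = umi / sample_umi_totals.reindex(umi.columns)
    n_sites = work.groupby("_variant")["site"].nunique().reindex(range(n), fill_value=0).to_numpy()
    n_tp = (
        work.dropna(subset=["timepoint"])
        .groupby("_variant")["timepoint"]
        .nunique()
        .reindex(range(n), fill_value=0)
        .to_numpy()
    )
    mean_shm = work.groupby("_variant")["shm_count"].mean().reindex(range(n)).to_numpy()
    frequency = share.sum(axis=1).to_numpy()
    variant_ids = [f"{clone_id}_v{i}" for i in range(n)]

    if n < 2:
        return CloneLineageGraph(
            clone_id=clone_id,
            variants=variant_seqs,
            variant_ids=variant_ids,
            abundance=share,
            distances=np.zeros((1, 1), dtype=int),
            edges=[],
            degrees=np.zeros(1, dtype=int),
            n_sites=n_sites,
            n_timepoints=n_tp,
            frequency=frequency,
            mean_shm=mean_shm,
            degenerate=True,
            trim_window=window,
        )

    dist = hamming_matrix(variant_seqs)
    edges = mst_edges(dist)
    deg = np.zeros(n, dtype=int)
    for i, j, _ in edges:
        deg[i] += 1
        deg[j] += 1
    return CloneLineageGraph(
        clone_id=clone_id,
        variants=variant_seqs,
        variant_ids=variant_ids,
        abundance=share,
        distances=dist,
        edges=edges,
        degrees=deg,
        n_sites=n_sites,
        n_timepoints=n_tp,
        frequency=frequency,
        mean_shm=mean_shm,
        trim_window=window,
    )


def annotate_occupancy(graph: CloneLineageGraph) -> pd.DataFrame:
    """Per-variant table: degree, sites/timepoints observed, summed frequency."""
    return pd.DataFrame(
        {
            "clone_id": graph.clone_id,
            "variant_id": graph.variant_ids,
            "degree": graph.degrees,
            "n_sites": graph.n_sites,
            "n_timepoints": graph.n_timepoints,
            "frequency": graph.frequency,
            "mean_shm": graph.mean_shm,
        }
    )


def centrality_analysis(
    df: pd.DataFrame,
    min_samples: int = 2,
    min_unique_seqs: int = 10,
    occupancy: float = 0.95,
    min_len: int = 80,
) -> tuple[pd.DataFrame, dict]:
    """Run the lineage-graph pipeline over all eligible clones of a table.

    ``df`` is a clone-assigned record table (one participant or several; the
    clone filter is applied per clone id). Returns the concatenated
    per-variant table and a dict of the retained :class:`CloneLineageGraph`.
    """
    from .clonotyping import clone_summary

    sample_totals = df.groupby("sample_id")["umi_count"].sum()
    retained = select_network_clones(
        clone_summary(df), min_samples=min_samples, min_unique_seqs=min_unique_seqs
    )
    graphs = {}
    tables = []
    for clone_id in retained:
        graph = build_clone_lineage_graph(
            df[df["clone_id"] == clone_id],
            sample_totals,
            occupancy=occupancy,
            min_len=min_len,
        )
        if graph is None or graph.degenerate:
            continue
        graphs[clone_id] = graph
        tables.append(annotate_occupancy(graph))
    variants = (
        pd.concat(tables, ignore_index=True)
        if tables
        else pd.DataFrame(
            columns=["clone_id", "variant_id", "degree", "n_sites", "n_timepoints", "frequency", "mean_shm"]
        )
    )
    return variants, graphs


def evaluate_degree_classifier(
    degrees,
    labels,
    cutoffs=DEFAULT_CUTOFFS,
) -> pd.DataFrame:
    """Sensitivity / specificity / accuracy of 'degree > cutoff' per cutoff.

    ``labels`` is the boolean per-variant truth (immunosurveilling: observed
    in >= 2 sites; persistent: >= 2 timepoints). With only one label class
    the undefined metric is reported as NaN.
    """
    deg = np.asarray(degrees)
    lab = np.asarray(labels, dtype=bool)
    rows = []
    for cutoff in cutoffs:
        pred = deg > cutoff
        tp = int((pred & lab).sum())
        tn = int((~pred & ~lab).sum())
        fp = int((pred & ~lab).sum())
        fn = int((~pred & lab).sum())
        rows.append(
            {
                "cutoff": cutoff,
                "sensitivity": tp / (tp + fn) if (tp + fn) else np.nan,
                "specificity": tn / (tn + fp) if (tn + fp) else np.nan,
                "accuracy": (tp + tn) / len(lab) if len(lab) else np.nan,
                "tp": tp,
                "tn": tn,
                "fp": fp,
                "fn": fn,
            }
        )
    return pd.DataFrame(rows)


def export_clone_network(graph: CloneLineageGraph) -> nx.Graph:
    """Plot-ready undirected MST: nodes carry abundance and degree, edges Hamming weight."""
    g = nx.Graph(clone_id=graph.clone_id)
    for i, vid in enumerate(graph.variant_ids):
        attrs = {
            "degree": int(graph.degrees[i]),
            "frequency": float(graph.frequency[i]),
            "n_sites": int(graph.n_sites[i]),
            "n_timepoints": int(graph.n_timepoints[i]),
        }
        for sample in graph.abundance.columns:
            attrs[f"share_{sample}"] = float(graph.abundance.loc[i, sample])
        g.add_node(vid, **attrs)
    for i, j, w in graph.edges:
        g.add_edge(graph.variant_ids[i], graph.variant_ids[j], weight=int(w))
    return g


def write_graphml(graph: CloneLineageGraph, path) -> None:
    nx.write_graphml(export_clone_network(graph), path)
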