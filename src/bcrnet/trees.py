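"""Clonal-similarity dendrograms and tree concordance testing.

Sharing matrices are turned into dendrograms by Ward-D2 agglomerative
clustering on the distance transform D = 1 - J. Concordance between two trees
over the same samples is the cophenetic correlation: the Pearson correlation
of the two inter-leaf cophenetic distance vectors. For dendrograms the
cophenetic distance of a leaf pair is the merge height of their lowest common
cluster; for edge-weighted trees (e.g. an externally supplied tumor mutational
phylogeny in Newick) it is the sum of branch lengths along the connecting
path. Significance uses a one-sided label-permutation test with an add-one
("permutations + 1") p-value, shuffling the labels of the second tree only
while keeping both topologies fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform


@dataclass
class LabeledTree:
    """A leaf-labelled tree: either a dendrogram or an edge-weighted phylogeny.

    Exactly one of ``linkage`` (scipy linkage matrix; merge-height cophenetic
    convention) or ``tree`` (dendropy Tree with branch lengths; path-sum
    convention) is set.
    """

    labels: list
    source: str = "BCR"
    linkage: np.ndarray | None = None
    tree: dendropy.Tree | None = None
    _coph: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if (self.linkage is None) == (self.tree is None):
            raise ValueError("exactly one of linkage/tree must be given")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("leaf labels must be unique")


def similarity_tree(jaccard, labels=None, source: str = "BCR") -> LabeledTree:
    """Ward-D2 dendrogram from a symmetric similarity (Jaccard) matrix.

    The distance transform is D = 1 - J. Raises on a non-symmetric input or
    values outside [0, 1].
    """
    if isinstance(jaccard, pd.DataFrame):
        labels = list(jaccard.index)
        mat = jaccard.to_numpy(dtype=float)
    else:
        mat = np.asarray(jaccard, dtype=float)
        if labels is None:
            labels = [str(i) for i in range(mat.shape[0])]
    if mat.shape[0] != mat.shape[1] or not np.allclose(mat, mat.T, atol=1e-8):
        raise ValueError("similarity matrix must be symmetric")
    if np.nanmin(mat) < -1e-9 or np.nanmax(mat) > 1 + 1e-9:
        raise ValueError("similarity values must lie in [0, 1]")
    dist = 1.0 - mat
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    # scipy 'ward' on a precomputed condensed distance matrix applies the
    # Lance-Williams Ward update to the given (unsquared) dissimilarities,
    # matching R hclust's ward.D2 criterion.
    linkage = hierarchy.linkage(condensed, method="ward")
    return LabeledTree(labels=list(labels), source=source, linkage=linkage)


def read_newick(path_or_str, source: str = "genomic") -> LabeledTree:
    """Read an edge-weighted tree (e.g. a tumor phylogeny) from Newick."""
    if isinstance(path_or_str, str) and path_or_str.lstrip().startswith("("):
        tree = dendropy.Tree.get(data=path_or_str, schema="newick")
    else:
        tree = dendropy.Tree.get(path=str(path_or_str), schema="newick")
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    return LabeledTree(labels=labels, source=source, tree=tree)


def to_newick(t: LabeledTree) -> str:
    """Serialize either tree kind to a Newick string with branch lengths."""
    if t.tree is not None:
        return t.tree.as_string(schema="newick").strip()
    root, _ = hierarchy.to_tree(t.linkage, rd=True)

    def _fmt(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{t.labels[node.id]}:{length:g}"
        left = _fmt(node.left, node.dist)
        right = _fmt(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return f"({_fmt(root.left, root.dist)},{_fmt(root.right, root.dist)});"


def cophenetic_matrix(t: LabeledTree) -> pd.DataFrame:
    """Square inter-leaf cophenetic distance matrix (labels as index/columns)."""
    if t._coph is not None:
        return pd.DataFrame(t._coph, index=t.labels, columns=t.labels)
    if t.linkage is not None:
        mat = squareform(hierarchy.cophenet(t.linkage))
    else:
        pdm = t.tree.phylogenetic_distance_matrix()
        taxa = {taxon.label: taxon for taxon in t.tree.taxon_namespace}
        n = len(t.labels)
        mat = np.zeros((n, n))
        for i, a in enumerate(t.labels):
            for j in range(i + 1, n):
                d = pdm.distance(taxa[a], taxa[t.labels[j]])
                mat[i, j] = mat[j, i] = d
    t._coph = mat
    return pd.DataFrame(mat, index=t.labels, columns=t.labels)


def _aligned_upper_triangles(tree_a: LabeledTree, tree_b: LabeledTree):
    if set(tree_a.labels) != set(tree_b.labels):
        raise ValueError("trees must have identical leaf label sets")
    order = sorted(tree_a.labels)
    ca = cophenetic_matrix(tree_a).loc[order, order].to_numpy()
    cb = cophenetic_matrix(tree_b).loc[order, order].to_numpy()
    iu = np.triu_indices(len(order), k=1)
    return ca[iu], cb[iu], order

def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    # degenerate (constant) distance vectors carry no ordering information
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def cophenetic_correlation(tree_a: LabeledTree, tree_b: LabeledTree) -> float:
    """Pearson correlation of the two cophenetic distance vectors, paired by leaf pair."""
    xa, xb, _ = _aligned_upper_triangles(tree_a, tree_b)
    return _pearson(xa, xb)


def permutation_pvalue(
    tree_a: LabeledTree,
    tree_b: LabeledTree,
    n_perm: int = 100,
    seed=0,
) -> tuple[float, float]:
    """One-sided label-permutation p-value for the cophenetic correlation.

    The labels of ``tree_b`` are shuffled ``n_perm`` times with both
    topologies held fixed; p = (1 + #{r_perm >= r_obs}) / (1 + n_perm), so
    p >= 1/(n_perm + 1) always. Returns (r_obs, p).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    xa, xb, order = _aligned_upper_triangles(tree_a, tree_b)
    n = len(order)
    cb = cophenetic_matrix(tree_b).loc[order, order].to_numpy()
    iu = np.triu_indices(n, k=1)
    r_obs = _pearson(xa, xb)

    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_perm = _pearson(xa, cb[np.ix_(perm, perm)][iu])
        if r_perm >= r_obs - 1e-12:
            n_ge += 1
    p = (1 + n_ge) / (1 + n_perm)
    return r_obs, float(p)


def write_cophenetic_csv(t: LabeledTree, path) -> None:
    cophenetic_matrix(t).to_csv(path)
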