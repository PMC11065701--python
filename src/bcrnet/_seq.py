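"""Shared low-level sequence helpers (uint8 encoding, pairwise Hamming)."""

from __future__ import annotations

import numpy as np


def encode_sequences(seqs) -> np.ndarray:
    """Encode equal-length strings as an (n, L) uint8 matrix of byte values."""
    seqs = list(seqs)
    if not seqs:
        return np.empty((0, 0), dtype=np.uint8)
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
    return np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8).reshape(
        len(seqs), lengths.pop()
    )


def pairwise_hamming(seqs, chunk: int = 256) -> np.ndarray:
    """Symmetric integer Hamming matrix over equal-length sequences.

    Every position with differing symbols counts 1; the gap character is an
    ordinary symbol (gap vs base = 1, gap vs gap = 0).
    """
    mat = encode_sequences(seqs)
    n = mat.shape[0]
    out = np.zeros((n, n), dtype=np.int64)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        block = (mat[start:stop, None, :] != mat[None, :, :]).sum(axis=2)
        out[start:stop, :] = block
    return out


def cross_hamming(a_seqs, b_seqs, chunk: int = 256) -> np.ndarray:
    """(len(a), len(b)) Hamming matrix between two equal-length sequence sets."""
    a = encode_sequences(a_seqs)
    b = encode_sequences(b_seqs)
    if a.size and b.size and a.shape[1] != b.shape[1]:
        raise ValueError("sequence sets have different lengths")
    out = np.zeros((a.shape[0], b.shape[0]), dtype=np.int64)
    for start in range(0, a.shape[0], chunk):
        stop = min(start + chunk, a.shape[0])
        out[start:stop, :] = (a[start:stop, None, :] != b[None, :, :]).sum(axis=2)
    return out


class UnionFind:
    """Array-backed disjoint sets with path compression."""

    def __init__(self, n: int):
        self.parent = np.arange(n)

    def find(self, i: int) -> int:
        p = self.parent
        root = i
        while p[root] != root:
            root = p[root]
        while p[i] != root:
            p[i], i = root, p[i]
        return root

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)

    def labels(self) -> np.ndarray:
        return np.array([self.find(i) for i in range(len(self.parent))])
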