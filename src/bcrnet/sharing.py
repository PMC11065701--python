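"""Depth-matched subsampled clonal sharing between samples.

Pairwise overlap of unique VDJ sequences (or clones) between two samples is
estimated by repeatedly subsampling both samples to a common depth — 90% of
the unique-sequence count of the shallowest sample — and taking the median
shared count / Jaccard coefficient over the iterations (default 10,000).
Subsampling operates on the set of unique VDJ sequences, not UMI-weighted.

Medians use the lower-median convention for even iteration counts, and every
pair draws from its own deterministic RNG substream so results do not depend
on the order pairs are computed in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

STATISTICS = ("count", "jaccard", "clone_count")


@dataclass
class SharingResult:
    sample_a: str
    sample_b: str
    statistic: str
    subsample_depth: int
    n_iterations: int
    median: float
    iqr: tuple


def subsample_depth(unique_counts, fraction: float = 0.9) -> int:
    """Common depth: floor(fraction x unique-sequence count of the shallowest sample)."""
    counts = list(unique_counts)
    if not counts:
        raise ValueError("no samples provided")
    if min(counts) < 1:
        raise ValueError("all unique-sequence counts must be >= 1")
    return int(np.floor(fraction * min(counts)))


def _lower_median(values: np.ndarray) -> float:
    return float(np.sort(values)[(len(values) - 1) // 2])


def _encode_pair(a, b):
    """Map two sequence sets onto shared integer codes."""
    a = np.asarray(a)
    b = np.asarray(b)
    universe, codes = np.unique(np.concatenate([a, b]), return_inverse=True)
    return codes[: len(a)], codes[len(a):], len(universe)


def shared_overlap(
    a,
    b,
    depth: int,
    n_iter: int = 10_000,
    statistic: str = "count",
    seed=0,
    a_clones=None,
    b_clones=None,
    name_a: str = "a",
    name_b: str = "b",
) -> SharingResult:
    """Median subsampled overlap between two samples' unique-sequence sets.

    Per iteration, ``depth`` unique sequences are drawn without replacement
    from each sample; the shared count is |A n B| and the Jaccard coefficient
    |A n B| / |A u B|. ``statistic='clone_count'`` instead intersects the
    clone-id sets of the drawn sequences (``a_clones``/``b_clones`` give the
    clone id parallel to each sequence).
    """
    if statistic not in STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    a = np.asarray(a)
    b = np.asarray(b)
    if depth > len(a) or depth > len(b):
        raise ValueError(f"depth {depth} exceeds a sample's unique count ({len(a)}, {len(b)})")
    if depth < 1:
        raise ValueError("depth must be >= 1")

    if statistic == "clone_count":
        if a_clones is None or b_clones is None:
            raise ValueError("clone_count requires a_clones and b_clones")
        a_codes, b_codes, _ = _encode_pair(np.asarray(a_clones), np.asarray(b_clones))
    else:
        a_codes, b_codes, _ = _encode_pair(a, b)

    rng = np.random.default_rng(seed)
    values = np.empty(n_iter, dtype=float)
    for it in range(n_iter):
        ia = rng.choice(len(a), size=depth, replace=False)
        ib = rng.choice(len(b), size=depth, replace=False)
        sub_a = a_codes[ia]
        sub_b = b_codes[ib]
        if statistic == "clone_count":
            inter = np.intersect1d(np.unique(sub_a), np.unique(sub_b), assume_unique=True).size
            values[it] = inter
        else:
            inter = np.intersect1d(sub_a, sub_b, assume_unique=True).size
            if statistic == "count":
                values[it] = inter
            else:
                union = 2 * depth - inter
                values[it] = inter / union

    q25, q75 = np.percentile(values, [25, 75])
    return SharingResult(
        sample_a=name_a,
        sample_b=name_b,
        statistic=statistic,
        subsample_depth=int(depth),
        n_iterations=int(n_iter),
        median=_lower_median(values),
        iqr=(float(q25), float(q75)),
    )


def _pair_seed(seed, i: int, j: int):
    # order-independent deterministic substream per unordered pair
    lo, hi = sorted((i, j))
    return [int(seed), lo, hi]


def sharing_matrix(
    sample_sets: dict,
    statistic: str = "jaccard",
    fraction: float = 0.9,
    n_iter: int = 10_000,
    seed=0,
    clone_maps: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All-pairs sharing over samples; returns (square matrix, long table).

    ``sample_sets`` maps sample_id -> array of unique VDJ sequences. The
    diagonal is 1 (jaccard), the common depth (count), or the sample's own
    clone count (clone_count). ``clone_maps`` maps sample_id -> clone ids
    parallel to the sequences (clone_count only).
    """
    names = list(sample_sets)
    if len(names) < 2:
        raise ValueError("sharing_matrix needs at least 2 samples")
    depth = subsample_depth([len(v) for v in sample_sets.values()], fraction=fraction)
    mat = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    rows = []
    for i, na in enumerate(names):
        for j in range(i + 1, len(names)):
            nb = names[j]
            res = shared_overlap(
                sample_sets[na],
                sample_sets[nb],
                depth=depth,
                n_iter=n_iter,
                statistic=statistic,
                seed=_pair_seed(seed, i, j),
                a_clones=None if clone_maps is None else clone_maps[na],
                b_clones=None if clone_maps is None else clone_maps[nb],
                name_a=na,
                name_b=nb,
            )
            mat.loc[na, nb] = mat.loc[nb, na] = res.median
            rows.append(
                {
                    "sample_a": na,
                    "sample_b": nb,
                    "statistic": statistic,
                    "depth": depth,
                    "median": res.median,
                    "iqr_low": res.iqr[0],
                    "iqr_high": res.iqr[1],
                }
            )
    for i, na in enumerate(names):
        if statistic == "jaccard":
            mat.loc[na, na] = 1.0
        elif statistic == "count":
            mat.loc[na, na] = float(depth)
        else:
            mat.loc[na, na] = float(
                len(np.unique(clone_maps[na])) if clone_maps is not None else np.nan
            )
    return mat, pd.DataFrame(rows)


def exact_jaccard(a, b) -> float:
    """Non-subsampled Jaccard over two unique-sequence sets (rank oracle)."""
    sa, sb = set(np.asarray(a).tolist()), set(np.asarray(b).tolist())
    if not sa and not sb:
        return 0.0
    return len(sa & sb) / len(sa | sb)
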