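"""Diversity indices, SHM categories, isotype usage and antigen experience.

Clonal expansion per sample is summarized by the Gini coefficient
(mean-absolute-difference form), Shannon entropy (natural log) and a
normalized mean clone size, each averaged over depth-matched UMI subsamples
(default 1,000 iterations). SHM counts are binned into no / low / high /
very-high categories, either at fixed thresholds (<=1, 2-10, 11-33, >33
mutations) or refitted with a 4-component Gaussian mixture on log(shm + 1).
Antigen-experienced BCRs are class switched (IgA/IgG/IgE) with more than
four mutations; inexperienced BCRs are unswitched (IgD/IgM) with four or
fewer.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .io import ISOTYPES, SWITCHED_ISOTYPES, UNSWITCHED_ISOTYPES

logger = logging.getLogger("bcrnet")

SHM_CATEGORIES = ("no", "low", "high", "very_high")
#: upper bounds (inclusive) for no / low / high; very_high is everything above
DEFAULT_SHM_THRESHOLDS = (1, 10, 33)


@dataclass
class DiversityResult:
    sample_id: str
    gini: float
    shannon: float
    mean_clone_size: float
    depth: int
    n_iterations: int


@dataclass
class ShmCategories:
    categories: pd.Series  # per record; NaN shm -> NaN category
    thresholds: tuple
    refit: bool = False


def gini(values) -> float:
    """Gini coefficient, mean-absolute-difference form: sum|xi-xj| / (2 n^2 mean)."""
    x = np.asarray(values, dtype=float)
    if len(x) == 0 or x.sum() == 0:
        return 0.0
    n = len(x)
    xs = np.sort(x)
    # sorted-rank identity for sum_{i,j} |xi - xj|
    diff_sum = 2 * ((2 * np.arange(1, n + 1) - n - 1) * xs).sum()
    return float(diff_sum / (2 * n**2 * x.mean()))


def shannon(values, normalized: bool = False) -> float:
    """Shannon entropy (natural log) of the clone-size distribution."""
    x = np.asarray(values, dtype=float)
    x = x[x > 0]
    if len(x) == 0:
        return 0.0
    p = x / x.sum()
    h = float(-(p * np.log(p)).sum())
    if normalized and len(p) > 1:
        h /= np.log(len(p))
    return h


def mean_clone_size(values, mode: str = "arithmetic") -> float:
    """Normalized mean clone size over clone UMI counts.

    ``arithmetic``: mean UMIs per clone divided by total UMIs (= 1/K at fixed
    depth; lower = more even). ``weighted``: UMI-weighted mean clone share,
    sum of squared proportions (Simpson-style).
    """
    x = np.asarray(values, dtype=float)
    x = x[x > 0]
    if len(x) == 0 or x.sum() == 0:
        return 0.0
    p = x / x.sum()
    if mode == "arithmetic":
        return float(x.mean() / x.sum())
    if mode == "weighted":
        return float((p**2).sum())
    raise ValueError(f"unknown mode {mode!r}")


def diversity(
    clone_umis,
    depth: int,
    n_iter: int = 1000,
    seed=0,
    sample_id: str = "",
    mean_mode: str = "arithmetic",
) -> DiversityResult:
    """Depth-matched diversity of one sample's clone UMI counts.

    Per iteration, ``depth`` UMIs are drawn without replacement (UMI-weighted,
    multivariate hypergeometric) and Gini, Shannon and normalized mean clone
    size are computed over the subsampled clone counts (clones absent from
    the subsample drop out). The per-index means across iterations are
    returned. When depth equals the full UMI count there is no subsampling
    randomness and the closed-form values are returned directly.
    """
    counts = np.asarray(clone_umis, dtype=np.int64)
    counts = counts[counts > 0]
    total = int(counts.sum())
    if depth > total:
        raise ValueError(f"depth {depth} exceeds sample UMI total {total}")
    if depth == total:
        return DiversityResult(
            sample_id=sample_id,
            gini=gini(counts),
            shannon=shannon(counts),
            mean_clone_size=mean_clone_size(counts, mode=mean_mode),
            depth=depth,
            n_iterations=1,
        )
    rng = np.random.default_rng(seed)
    g = np.empty(n_iter)
    h = np.empty(n_iter)
    m = np.empty(n_iter)
    for it in range(n_iter):
        sub = rng.multivariate_hypergeometric(counts, depth)
        sub = sub[sub > 0]
        g[it] = gini(sub)
        h[it] = shannon(sub)
        m[it] = mean_clone_size(sub, mode=mean_mode)
    return DiversityResult(
        sample_id=sample_id,
        gini=float(g.mean()),
        shannon=float(h.mean()),
        mean_clone_size=float(m.mean()),
        depth=int(depth),
        n_iterations=int(n_iter),
    )


def _categorize(shm: pd.Series, thresholds) -> pd.Series:
    t1, t2, t3 = thresholds
    bins = [-np.inf, t1, t2, t3, np.inf]
    return pd.cut(shm, bins=bins, labels=SHM_CATEGORIES).astype(object)


def classify_shm(shm_counts, mode: str = "fixed", seed=0, thresholds=DEFAULT_SHM_THRESHOLDS) -> ShmCategories:
    """Bin SHM counts into no / low / high / very_high.

    ``fixed`` applies the default thresholds. ``refit`` fits a 4-component
    Gaussian mixture on log(shm + 1) and derives the three posterior-crossing
    thresholds between adjacent components (falling back to ``fixed`` with a
    warning below 200 records). "Highly mutated" = high or very_high.
    """
    shm = pd.Series(shm_counts, dtype=float)
    valid = shm.dropna()
    if mode == "fixed":
        return ShmCategories(_categorize(shm, thresholds), tuple(thresholds), refit=False)
    if mode != "refit":
        raise ValueError(f"unknown mode {mode!r}")
    if len(valid) < 200:
        logger.warning("refit requested with %d records (< 200); using fixed thresholds", len(valid))
        return ShmCategories(_categorize(shm, thresholds), tuple(thresholds), refit=False)

    logx = np.log1p(valid.to_numpy())
    gmm = GaussianMixture(
        n_components=4, n_init=10, init_params="k-means++", random_state=int(seed) % (2**31)
    ).fit(logx.reshape(-1, 1))
    means = gmm.means_.ravel()
    sds = np.sqrt(gmm.covariances_.ravel())
    weights = gmm.weights_.ravel()
    order = np.argsort(means)
    grid = np.linspace(logx.min(), logx.max(), 4001)
    dens = np.stack(
        [w / s * np.exp(-0.5 * ((grid - m) / s) ** 2) for m, s, w in zip(means, sds, weights)]
    )
    resp = dens / dens.sum(axis=0, keepdims=True)
    cuts = []
    for lower, upper in zip(order[:-1], order[1:]):
        window = (grid >= means[lower]) & (grid <= means[upper])
        idx = np.nonzero(window & (resp[upper] >= resp[lower]))[0]
        cut_log = grid[idx[0]] if len(idx) else (means[lower] + means[upper]) / 2
        cuts.append(float(np.expm1(cut_log)))
    return ShmCategories(_categorize(shm, cuts), tuple(cuts), refit=True)


def isotype_usage(sample_df: pd.DataFrame) -> pd.Series:
    """UMI-weighted isotype proportions for one sample, plus the unswitched total.

    Proportions sum to 1 over known isotypes; ``unswitched`` = IGHD + IGHM.
    All-unknown input yields an empty result with a warning.
    """
    igh = sample_df[sample_df["chain"] == "IGH"]
    known = igh[igh["isotype"].isin(ISOTYPES)]
    if known.empty:
        logger.warning("no records with known isotype")
        return pd.Series(dtype=float)
    umis = known.groupby("isotype")["umi_count"].sum().reindex(ISOTYPES, fill_value=0)
    props = umis / umis.sum()
    props["unswitched"] = props[list(UNSWITCHED_ISOTYPES)].sum()
    return props


def antigen_experience(isotype, shm_count) -> str:
    """experienced: class switched and > 4 mutations; inexperienced: unswitched and <= 4."""
    if isotype is None or shm_count is None or pd.isna(shm_count):
        return "unclassified"
    if isotype in SWITCHED_ISOTYPES and shm_count > 4:
        return "experienced"
    if isotype in UNSWITCHED_ISOTYPES and shm_count <= 4:
        return "inexperienced"
    return "unclassified"


def annotate_antigen_experience(df: pd.DataFrame) -> pd.Series:
    return pd.Series(
        [antigen_experience(i, s) for i, s in zip(df["isotype"], df["shm_count"])],
        index=df.index,
        name="antigen_experience",
    )


def mean_sample_shm(sample_df: pd.DataFrame) -> float:
    """Two-stage mean SHM: mean per clone first, then mean over clones.

    The unweighted mean over per-clone means keeps large clones from being
    overrepresented; generally different from the flat per-record mean.
    """
    valid = sample_df.dropna(subset=["shm_count"])
    if valid.empty:
        return float("nan")
    per_clone = valid.groupby("clone_id")["shm_count"].mean()
    return float(per_clone.mean())


def high_low_split(values: pd.Series) -> pd.Series:
    """Median (50th percentile) split: 'high' > median, 'low' <= median."""
    cutoff = values.quantile(0.5)
    return pd.Series(np.where(values > cutoff, "high", "low"), index=values.index)
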