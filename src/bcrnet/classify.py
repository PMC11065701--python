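"""Clone topology classes, the expansion threshold, and clone classes A-D.

Within each participant with two or more samples, a clone is *stem* if seen
in every sample, *clade* if seen in more than one but not all, and *private*
if seen in exactly one; stem and clade clones are the immunosurveilling /
temporally persistent ones. Clone size is the fraction of a sample's UMIs
belonging to the clone. A single expansion cutoff on the log10 percent-UMI
scale is fitted by a Gaussian mixture over all clone-sample sizes pooled
across samples, taking the posterior-equality crossing between the top
component and the rest, adjusted upward if needed so that expanded
observations stay below 10% of the repertoire. The four clone classes are
A: private expanded, B: shared expanded, C: private unexpanded,
D: shared unexpanded; a clone above the cutoff in at least one sample counts
as expanded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

logger = logging.getLogger("bcrnet")

TOPOLOGIES = ("stem", "clade", "private")
CLONE_CLASSES = ("A", "B", "C", "D")


@dataclass
class ExpansionModel:
    """Fitted mixture on log10 percent clone sizes and the derived cutoff."""

    means: np.ndarray
    sds: np.ndarray
    weights: np.ndarray
    cutoff: float  # log10 percent UMI scale
    fallback: bool = False

    def is_expanded(self, log10_percent) -> np.ndarray:
        return np.asarray(log10_percent, dtype=float) > self.cutoff

    def to_dict(self) -> dict:
        return {
            "means": self.means.tolist(),
            "sds": self.sds.tolist(),
            "weights": self.weights.tolist(),
            "cutoff": float(self.cutoff),
            "fallback": bool(self.fallback),
        }


def clone_proportions(clone_umis: pd.DataFrame) -> pd.DataFrame:
    """Per-clone per-sample UMI proportions (clone x sample; columns sum to 1).

    ``clone_umis`` is a clone x sample matrix of UMI counts (0 = absent).
    Raises on a sample with zero total UMIs.
    """
    totals = clone_umis.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"sample(s) with zero UMIs: {bad}")
    return clone_umis / totals


def classify_topology(presence: pd.DataFrame, n_participant_samples: int) -> pd.Series:
    """Stem / clade / private from a clone x sample presence matrix.

    ``presence`` covers all samples of one participant (column per sample).
    Participants with a single sample cannot be classified; their clones are
    labelled ``unclassifiable`` and are excluded from class analyses.
    """
    observed = (presence > 0).sum(axis=1)
    if n_participant_samples < 2:
        return pd.Series("unclassifiable", index=presence.index, name="topology")
    topo = pd.Series("private", index=presence.index, name="topology")
    topo[observed > 1] = "clade"
    topo[observed == n_participant_samples] = "stem"
    return topo


def _posterior_crossing(gmm_means, gmm_sds, gmm_weights, lo, hi):
    """Smallest x in [lo, hi] where the top-mean component's posterior reaches 0.5."""
    order = np.argsort(gmm_means)
    top = order[-1]
    grid = np.linspace(lo, hi, 4001)
    log_dens = np.stack(
        [
            np.log(w) - 0.5 * ((grid - m) / s) ** 2 - np.log(s)
            for m, s, w in zip(gmm_means, gmm_sds, gmm_weights)
        ]
    )
    log_dens -= log_dens.max(axis=0, keepdims=True)
    dens = np.exp(log_dens)
    post_top = dens[top] / dens.sum(axis=0)
    above = np.nonzero(post_top >= 0.5)[0]
    if len(above) == 0:
        return None
    return float(grid[above[0]])


def fit_expansion_threshold(
    log10_percent,
    n_components: int = 2,
    seed: int = 0,
    max_expanded_fraction: float = 0.10,
    clone_ids=None,
    select_bic: bool = False,
    max_components: int = 4,
) -> ExpansionModel:
    """Fit the expansion cutoff on pooled log10 percent clone sizes.

    Fits a Gaussian mixture (k-means++-seeded, 10 restarts); the candidate
    cutoff is the posterior-equality crossing between the top component and
    the rest, raised to the 1 - ``max_expanded_fraction`` quantile if the
    expanded fraction of the repertoire would otherwise reach that bound.
    When ``clone_ids`` (parallel to the pooled values) is given, the expanded
    fraction counts distinct clones above the cutoff in any sample; otherwise
    it is the fraction of observations above the cutoff. Degenerate mixtures
    (components closer than half the pooled s.d.) fall back to the 90th
    percentile with a warning. Requires >= 100 observations.
    """
    x = np.asarray(log10_percent, dtype=float)
    keep = np.isfinite(x)
    x = x[keep]
    if clone_ids is not None:
        clone_ids = np.asarray(clone_ids)[keep]
    if len(x) < 100:
        raise ValueError(f"need >= 100 clone-size observations, got {len(x)}")

    def _expanded_fraction(cut: float) -> float:
        if clone_ids is None:
            return float(np.mean(x > cut))
        above = pd.Series(x > cut).groupby(pd.Series(clone_ids)).any()
        return float(above.mean())

    def _fit(k):
        gmm = GaussianMixture(
            n_components=k,
            n_init=10,
            init_params="k-means++",
            random_state=int(seed) % (2**31),
        )
        gmm.fit(x.reshape(-1, 1))
        return gmm

    if select_bic:
        fits = [_fit(k) for k in range(2, max_components + 1)]
        gmm = min(fits, key=lambda g: g.bic(x.reshape(-1, 1)))
    else:
        gmm = _fit(n_components)

    means = gmm.means_.ravel()
    sds = np.sqrt(gmm.covariances_.ravel())
    weights = gmm.weights_.ravel()

    pooled_sd = float(np.std(x))
    sep = np.max(means) - np.min(means)
    # degenerate if the components (nearly) coincide, or if one component
    # explains the data at least as well (BIC)
    fallback = sep < 0.5 * pooled_sd or _fit(1).bic(x.reshape(-1, 1)) <= gmm.bic(x.reshape(-1, 1))
    cutoff = None
    if not fallback:
        cutoff = _posterior_crossing(means, sds, weights, float(np.min(means)), float(np.max(x)))
        fallback = cutoff is None
    if fallback:
        cutoff = float(np.quantile(x, 1 - max_expanded_fraction))
        logger.warning(
            "degenerate mixture (component separation %.3f < %.3f); "
            "falling back to the %.0fth-percentile cutoff",
            sep,
            0.5 * pooled_sd,
            100 * (1 - max_expanded_fraction),
        )
    # expanded clones must stay a small minority of the repertoire
    if _expanded_fraction(cutoff) >= max_expanded_fraction:
        cutoff = float(np.quantile(x, 1 - max_expanded_fraction))
        if _expanded_fraction(cutoff) >= max_expanded_fraction:
            # clone-level fraction can exceed the value quantile; push upward
            for q in np.linspace(1 - max_expanded_fraction, 1.0, 50):
                cutoff = float(np.quantile(x, q))
                if _expanded_fraction(cutoff) < max_expanded_fraction:
                    break
    return ExpansionModel(means=means, sds=sds, weights=weights, cutoff=float(cutoff), fallback=bool(fallback))


def classify_clone_class(topology: str, expanded: bool) -> str:
    """A: private expanded, B: shared expanded, C: private unexpanded, D: shared unexpanded."""
    if topology not in TOPOLOGIES:
        return "unclassifiable"
    private = topology == "private"
    if expanded:
        return "A" if private else "B"
    return "C" if private else "D"


def annotate_clones(
    proportions: pd.DataFrame,
    topology: pd.Series,
    model: ExpansionModel,
) -> pd.DataFrame:
    """Per-clone annotation table: topology, expanded flag, clone class.

    A clone is expanded iff its size is above the cutoff in at least one
    sample (max-over-samples rule). Stem and clade clones are flagged
    immunosurveilling/persistent.
    """
    with np.errstate(divide="ignore"):
        log10_pct = np.log10(100.0 * proportions.where(proportions > 0))
    max_log10 = log10_pct.max(axis=1)
    expanded = max_log10 > model.cutoff
    topo = topology.reindex(proportions.index)
    out = pd.DataFrame(
        {
            "topology": topo,
            "n_samples_observed": (proportions > 0).sum(axis=1),
            "max_log10_percent": max_log10,
            "expanded": expanded,
            "immunosurveilling": topo.isin(["stem", "clade"]),
        }
    )
    out["clone_class"] = [
        classify_clone_class(t, e) for t, e in zip(out["topology"], out["expanded"])
    ]
    out.index.name = "clone_id"
    return out


def surveilling_site_proportions(
    unique_vdjs: pd.DataFrame,
    sample_sites: pd.Series,
    min_vdjs: int = 4,
) -> pd.Series:
    """Per-site mean share of immunosurveilling clones' unique VDJs.

    ``unique_vdjs`` is a clone x sample matrix of unique VDJ counts;
    ``sample_sites`` maps sample_id -> site. Clones present in more than one
    site with at least ``min_vdjs`` unique VDJs in at least one sample are
    retained; each clone's per-sample VDJ counts are normalized to proportions
    (summing to 1 across samples) and averaged per site.
    """
    sites = sample_sites.reindex(unique_vdjs.columns)
    by_site = unique_vdjs.T.groupby(sites).sum().T  # clone x site
    multi_site = (by_site > 0).sum(axis=1) > 1
    deep_enough = unique_vdjs.max(axis=1) >= min_vdjs
    keep = unique_vdjs[multi_site & deep_enough]
    if keep.empty:
        logger.warning("no clone passes the immunosurveilling-clone filter")
        return pd.Series(dtype=float, name="mean_proportion")
    props = keep.div(keep.sum(axis=1), axis=0)  # clone x sample, rows sum to 1
    per_site = props.T.groupby(sites).sum().T  # clone x site proportions
    return per_site.mean(axis=0).rename("mean_proportion")
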