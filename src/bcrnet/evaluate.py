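"""Recovery evaluation of the pipeline against the generator's planted truth.

Shared by the benchmark tests and the reproduction script: runs clonotyping,
expansion-threshold fitting and the degree-centrality classifier on a
simulated repertoire and measures how well each planted quantity is
recovered (clonotyping agreement, cutoff error against the planted component
boundary, classifier metrics against planted hub dissemination, and the
degree / site-count / SHM rank associations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import kendalltau, norm
from sklearn.metrics import adjusted_rand_score

from .centrality import centrality_analysis, evaluate_degree_classifier
from .classify import ExpansionModel, clone_proportions, fit_expansion_threshold
from .clonotyping import assign_clones, clone_sample_umis
from .io import Repertoire
from .simulate import SimConfig


def assign_all(rep: Repertoire, **kwargs) -> pd.DataFrame:
    """Clone-assign every participant's records (clonotyping is per participant)."""
    pieces = [assign_clones(g, **kwargs) for _, g in rep.df.groupby("participant_id")]
    return pd.concat(pieces, ignore_index=True)


def _truth_key(frame: pd.DataFrame) -> pd.Series:
    return frame["participant_id"].astype(str) + ":" + frame["sequence_id"].astype(str)


def clonotyping_ari(df: pd.DataFrame, truth: pd.DataFrame) -> float:
    """Adjusted Rand index between predicted clone ids and planted lineages."""
    tmap = dict(zip(_truth_key(truth), truth["true_clone_id"]))
    true_labels = _truth_key(df).map(tmap)
    return float(adjusted_rand_score(true_labels.to_numpy(), df["clone_id"].to_numpy()))


def pooled_clone_sizes(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Pooled log10 percent clone-sample sizes and parallel global clone ids."""
    vals, clones = [], []
    for pid, g in df.groupby("participant_id"):
        props = clone_proportions(clone_sample_umis(g))
        with np.errstate(divide="ignore"):
            x = np.log10(100.0 * props.where(props > 0)).stack().dropna()
        vals.append(x.to_numpy())
        clones.extend(f"{pid}:{c}" for c, _ in x.index)
    return np.concatenate(vals), np.asarray(clones)


def planted_size_boundary(cfg: SimConfig, rep: Repertoire, truth: pd.DataFrame) -> float:
    """Planted expanded/unexpanded boundary on the realized log10 percent scale.

    The generator draws clone sizes on a nominal percent scale; per-sample
    normalization shifts every clone by the same offset. The offset is
    estimated as the mean difference between realized truth-clone
    log-proportions and the drawn sizes, and the boundary is the
    posterior-equality crossing of the two planted components on that
    realized scale.
    """
    tmap = dict(zip(_truth_key(truth), truth["true_clone_id"]))
    drawn = truth.drop_duplicates("true_clone_id").set_index("true_clone_id")["clone_log10_size"]
    offsets = []
    work = rep.df.copy()
    work["_tclone"] = _truth_key(work).map(tmap)
    for _, g in work.groupby("participant_id"):
        umis = g.pivot_table(
            index="_tclone", columns="sample_id", values="umi_count", aggfunc="sum", fill_value=0
        )
        props = umis / umis.sum(axis=0)
        with np.errstate(divide="ignore"):
            x = np.log10(100.0 * props.where(props > 0)).stack().dropna()
        for (clone, _), v in x.items():
            offsets.append(v - drawn[clone])
    gamma = float(np.mean(offsets))

    mu, su = cfg.unexpanded_size
    me, se = cfg.expanded_size
    su = float(np.hypot(su, cfg.site_size_jitter_sd))
    se = float(np.hypot(se, cfg.site_size_jitter_sd))
    w = cfg.expanded_fraction
    grid = np.linspace(mu + gamma, me + gamma, 4001)
    f_exp = w * norm.pdf(grid, me + gamma, se)
    f_un = (1 - w) * norm.pdf(grid, mu + gamma, su)
    return float(grid[np.argmin(np.abs(f_exp - f_un))])


def expanded_recall(model: ExpansionModel, rep: Repertoire, truth: pd.DataFrame) -> float:
    """Fraction of planted expanded clones whose realized max size exceeds the cutoff."""
    tmap = dict(zip(_truth_key(truth), truth["true_clone_id"]))
    flags = truth.drop_duplicates("true_clone_id").set_index("true_clone_id")["expanded_clone"]
    work = rep.df.copy()
    work["_tclone"] = _truth_key(work).map(tmap)
    hits = []
    for _, g in work.groupby("participant_id"):
        umis = g.pivot_table(
            index="_tclone", columns="sample_id", values="umi_count", aggfunc="sum", fill_value=0
        )
        props = umis / umis.sum(axis=0)
        with np.errstate(divide="ignore"):
            mx = np.log10(100.0 * props.where(props > 0)).max(axis=1)
        for clone, v in mx.items():
            if flags[clone]:
                hits.append(bool(v > model.cutoff))
    return float(np.mean(hits)) if hits else float("nan")


@dataclass
class RecoveryReport:
    ari: float
    cutoff: float
    planted_boundary: float
    cutoff_error: float
    expanded_recall: float
    classifier: pd.DataFrame
    accuracy_cutoff2: float
    best_constant_accuracy: float
    tau_degree_sites: float
    tau_degree_sites_p: float
    tau_degree_shm: float
    n_variants: int
    n_clone_size_obs: int


def recovery_report(rep: Repertoire, truth: pd.DataFrame, cfg: SimConfig, seed: int = 0) -> RecoveryReport:
    """Full planted-truth recovery run on one simulated repertoire."""
    df = assign_all(rep)
    ari = clonotyping_ari(df, truth)

    x, clone_ids = pooled_clone_sizes(df)
    model = fit_expansion_threshold(x, seed=seed, clone_ids=clone_ids)
    boundary = planted_size_boundary(cfg, rep, truth)
    recall = expanded_recall(model, rep, truth)

    variants, _ = centrality_analysis(df)
    labels = variants["n_sites"] >= 2
    metrics = evaluate_degree_classifier(variants["degree"], labels)
    acc2 = float(metrics.loc[metrics["cutoff"] == 2, "accuracy"].iloc[0])
    best_const = float(max(labels.mean(), 1 - labels.mean()))
    tau_s = kendalltau(variants["degree"], variants["n_sites"])
    tau_m = kendalltau(variants["degree"], variants["mean_shm"])

    return RecoveryReport(
        ari=ari,
        cutoff=float(model.cutoff),
        planted_boundary=boundary,
        cutoff_error=float(abs(model.cutoff - boundary)),
        expanded_recall=recall,
        classifier=metrics,
        accuracy_cutoff2=acc2,
        best_constant_accuracy=best_const,
        tau_degree_sites=float(tau_s.statistic),
        tau_degree_sites_p=float(tau_s.pvalue),
        tau_degree_shm=float(tau_m.statistic),
        n_variants=int(len(variants)),
        n_clone_size_obs=int(len(x)),
    )


def classifier_accuracy(rep: Repertoire, cutoff: int = 2) -> tuple[float, int]:
    """Degree-classifier accuracy (immunosurveilling label) on one repertoire."""
    df = assign_all(rep)
    variants, _ = centrality_analysis(df)
    metrics = evaluate_degree_classifier(variants["degree"], variants["n_sites"] >= 2, cutoffs=(cutoff,))
    return float(metrics["accuracy"].iloc[0]), int(len(variants))
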