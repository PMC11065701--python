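"""Synthetic multi-site BCR repertoires with planted ground truth.

Generates multi-participant repertoires whose statistical structure mirrors
the assumptions of the analysis pipeline: clonal lineages related by point
mutations (substitution-only; the clone-assembly edge rule is non-indel),
heavy-tailed two-component clone sizes (expanded vs unexpanded, lognormal on
the log10 percent-UMI scale), class switching whose probability rises with
lineage depth, and a planted subset of lineage-internal *hub* variants that
are disseminated across several sites and timepoints while every other
variant stays in a single site.

Each clone's lineage tree is grown by sequential random attachment: new
variants attach preferentially to planted hubs, otherwise to the tip of an
existing chain, and only rarely to a chain interior. Hubs therefore acquire
many children (high MST degree) and multi-site occupancy, giving every
pipeline stage — clonotyping, expansion-threshold fitting, topology classes,
and the degree-centrality classifier — a known truth to recover. Hub
positions are drawn uniformly over variant indices, independent of lineage
depth, so degree is independent of SHM by construction.

One designated hub-origin site (lymph node by default) hosts most clone
roots and exploratory chains, emulating lymph nodes as the main source of
clonal diversification.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .io import Repertoire

logger = logging.getLogger("bcrnet")

NT = np.array(list("ACGT"))

DEFAULT_SITES = (
    "lymph_node",
    "liver",
    "lung_pleura",
    "breast",
    "brain",
    "skin",
    "bone",
    "peritoneum",
)

SWITCHED_CHOICES = ("IGHG1", "IGHA1", "IGHG2", "IGHG3", "IGHA2", "IGHG4", "IGHE")
SWITCHED_PROBS = (0.35, 0.30, 0.10, 0.08, 0.08, 0.04, 0.05)

#: retained per-antigen composition of the packaged *synthetic* reference
#: antibody table (total 5,800 entries)
REFERENCE_DB_COMPOSITION = {
    "human immunodeficiency virus-1": 3525,
    "Clostridium tetani": 817,
    "influenza A": 486,
    "vaccinia virus": 92,
    "hepatitis C virus": 80,
    "Streptococcus pneumoniae": 59,
    "Staphylococcus aureus": 38,
    "human betaherpesvirus 5": 32,
    "other": 671,
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic repertoire generator.

    Clone sizes are drawn on the log10 percent-UMI scale from a two-component
    model (unexpanded / expanded); per-edge mutation counts are geometric
    with mean ``mutation_mean`` at uniform random positions; ``hub_fraction``
    of an eligible clone's variants become cross-site hubs whose dissemination
    breadth is ``2 + Poisson(hub_breadth_rate)`` sites.
    """

    n_participants: int = 2
    sites: tuple = DEFAULT_SITES
    n_timepoints: int = 3
    n_clones: int = 300
    germline_len: int = 351
    cdr3_start: int = 285  # codon-aligned; CDR3 spans [cdr3_start, cdr3_start + cdr3_len)
    cdr3_len: int = 60
    n_v_genes: int = 30
    expanded_fraction: float = 0.06
    unexpanded_size: tuple = (-1.45, 0.30)  # mean, sd of log10 percent UMIs
    expanded_size: tuple = (0.30, 0.25)
    expanded_min_variants: int = 15
    expanded_extra_variants_mean: float = 60.0
    unexpanded_variant_p: float = 0.55  # geometric parameter for small-clone sizes
    branching_rate: float = 1.0  # scales extra variants per clone; 0 = germline only
    mutation_mean: float = 1.2
    baseline_shm_shape: float = 1.2  # clone-level baseline SHM ~ Poisson(Gamma(shape, scale))
    baseline_shm_scale: float = 14.0
    hub_fraction: float = 0.05
    hub_breadth_rate: float = 0.7
    attach_weight_hub: float = 6.0
    attach_weight_tip: float = 1.0
    attach_weight_interior: float = 0.03
    migrate_prob: float = 0.08  # chain hand-off to another clone site (non-hub)
    csr_rate: float = 0.25  # P(switch) = 1 - exp(-csr_rate * depth)
    hub_origin_site: str = "lymph_node"
    hub_origin_prob: float = 0.5
    p_unexpanded_second_site: float = 0.2
    umi_per_sample: int = 20000
    hub_umi_weight: float = 6.0
    site_size_jitter_sd: float = 0.10  # per-site wobble of a clone's log10 size
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.hub_fraction <= 1):
            raise ValueError("hub_fraction must be in [0, 1]")
        if self.germline_len < 80:
            raise ValueError("germline_len must be >= 80")
        if self.mutation_mean < 1:
            raise ValueError("mutation_mean must be >= 1 (count per edge)")
        for name in ("branching_rate", "csr_rate", "hub_breadth_rate", "migrate_prob"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_clones < 1 or self.n_participants < 1:
            raise ValueError("need at least one clone and one participant")
        if self.cdr3_start % 3 or self.cdr3_len % 3:
            raise ValueError("CDR3 window must be codon-aligned")
        if self.cdr3_start + self.cdr3_len > self.germline_len:
            raise ValueError("CDR3 window exceeds germline length")


def _translate(seq_nt: str) -> str:
    return str(Seq(seq_nt).translate())


def _random_germline(rng, cfg: SimConfig) -> str:
    """Random germline with a stop-free CDR3 window."""
    while True:
        seq = "".join(rng.choice(NT, size=cfg.germline_len))
        cdr3 = seq[cfg.cdr3_start : cfg.cdr3_start + cfg.cdr3_len]
        if "*" not in _translate(cdr3):
            return seq


def _mutate(rng, seq: list, cfg: SimConfig, k: int | None = None) -> tuple[list, int]:
    """Apply k substitutions (geometric draw by default); keep the CDR3 stop-free."""
    if k is None:
        k = int(rng.geometric(1.0 / cfg.mutation_mean))
    out = list(seq)
    applied = 0
    guard = 0
    while applied < k and guard < 100 * k + 100:
        guard += 1
        pos = int(rng.integers(cfg.germline_len))
        old = out[pos]
        new = str(rng.choice(NT[NT != old]))
        out[pos] = new
        if cfg.cdr3_start <= pos < cfg.cdr3_start + cfg.cdr3_len:
            cdr3 = "".join(out[cfg.cdr3_start : cfg.cdr3_start + cfg.cdr3_len])
            if "*" in _translate(cdr3):
                out[pos] = old  # re-draw a mutation that creates a stop codon
                continue
        applied += 1
    return out, applied


def _grow_tree(rng, n: int, hubs: set, cfg: SimConfig) -> list[int]:
    """Parent index per node (root = -1) by weighted sequential attachment.

    A hub that does not yet have two children takes the next arrivals with
    priority, so every planted hub becomes a genuine branch point; afterwards
    attachment is weighted (hubs > chain tips >> chain interiors).
    """
    parents = [-1]
    n_children = np.zeros(n, dtype=int)
    for i in range(1, n):
        deficit = [h for h in sorted(hubs) if h < i and n_children[h] < 2]
        if deficit:
            parent = deficit[0]
        else:
            weights = np.empty(i)
            for j in range(i):
                if j in hubs:
                    weights[j] = cfg.attach_weight_hub
                elif n_children[j] == 0:
                    weights[j] = cfg.attach_weight_tip
                else:
                    weights[j] = cfg.attach_weight_interior
            parent = int(rng.choice(i, p=weights / weights.sum()))
        parents.append(parent)
        n_children[parent] += 1
    return parents


def simulate(config: SimConfig | None = None, seed=None) -> tuple[Repertoire, pd.DataFrame]:
    """Generate a repertoire and its ground truth under the given conditions.

    Returns ``(repertoire, truth)``; ``truth`` has one row per simulated
    variant with its true clone id, parent, depth, summed edge-mutation SHM,
    hub flag, sites and timepoints, and its clone's expanded flag. Raises if
    the configuration would produce no sequences.
    """
    cfg = config or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    site_list = list(cfg.sites)
    meta_rows = []
    record_rows = []
    truth_rows = []
    collisions = 0

    for p in range(cfg.n_participants):
        pid = f"P{p + 1}"
        sample_of_site = {site: f"{pid}_{site}" for site in site_list}
        timepoint_of_site = {site: i % cfg.n_timepoints for i, site in enumerate(site_list)}
        for i, site in enumerate(site_list):
            meta_rows.append(
                {
                    "sample_id": sample_of_site[site],
                    "participant_id": pid,
                    "site": site,
                    "timepoint": timepoint_of_site[site],
                }
            )

        # per-sample emission buffers: (clone, variant, weight, row template)
        emitted: dict[str, list] = {s: [] for s in sample_of_site.values()}

        for c in range(cfg.n_clones):
            clone_truth_id = f"{pid}_c{c:04d}"
            v_gene = f"IGHV{int(rng.integers(1, 8))}-{int(rng.integers(1, 1 + cfg.n_v_genes // 7))}"
            germline = _random_germline(rng, cfg)
            expanded = bool(rng.random() < cfg.expanded_fraction)

            mean, sd = cfg.expanded_size if expanded else cfg.unexpanded_size
            log10_pct = float(rng.normal(mean, sd))
            clone_weight = 10.0**log10_pct

            if expanded:
                n_var = cfg.expanded_min_variants + int(rng.poisson(cfg.expanded_extra_variants_mean))
            else:
                n_var = int(rng.geometric(cfg.unexpanded_variant_p))
            n_var = 1 + int(round(cfg.branching_rate * (n_var - 1)))

            # clone site set: origin plus extra sites for shared clones
            if rng.random() < cfg.hub_origin_prob and cfg.hub_origin_site in site_list:
                origin = cfg.hub_origin_site
            else:
                origin = site_list[int(rng.integers(len(site_list)))]
            others = [s for s in site_list if s != origin]
            if expanded:
                n_extra = min(len(others), 1 + int(rng.poisson(1.0)))
            else:
                n_extra = 1 if (rng.random() < cfg.p_unexpanded_second_site and others) else 0
            extra = list(rng.choice(others, size=n_extra, replace=False)) if n_extra else []
            clone_sites = [origin] + extra

            hubs: set[int] = set()
            if n_var >= 10 and len(clone_sites) >= 2 and cfg.hub_fraction > 0:
                n_hubs = max(1, int(round(cfg.hub_fraction * n_var)))
                hubs = set(int(x) for x in rng.choice(np.arange(1, n_var), size=min(n_hubs, n_var - 1), replace=False))

            parents = _grow_tree(rng, n_var, hubs, cfg)

            # the observed root already carries clone-level baseline SHM from
            # affinity maturation preceding the sampled lineage
            baseline = int(rng.poisson(rng.gamma(cfg.baseline_shm_shape, cfg.baseline_shm_scale)))
            if baseline:
                root_seq, baseline = _mutate(rng, list(germline), cfg, k=baseline)
            else:
                root_seq = list(germline)
            seqs = [root_seq]
            depths = [0]
            shms = [baseline]
            # a shared clone without planted hubs is seeded by its founder in
            # every clone site (the clone, not a lineage hub, migrated)
            if not hubs and len(clone_sites) > 1:
                node_sites: list[list[str]] = [list(clone_sites)]
            else:
                node_sites = [[origin]]
            for v in range(1, n_var):
                parent = parents[v]
                seq, k = _mutate(rng, seqs[parent], cfg)
                seqs.append(seq)
                depths.append(depths[parent] + 1)
                shms.append(shms[parent] + k)
                parent_primary = node_sites[parent][0]
                if v in hubs:
                    breadth = min(len(clone_sites), 2 + int(rng.poisson(cfg.hub_breadth_rate)))
                    pool = [s for s in clone_sites if s != parent_primary]
                    picked = list(rng.choice(pool, size=breadth - 1, replace=False)) if breadth > 1 else []
                    node_sites.append([parent_primary] + picked)
                elif parents[v] in hubs:
                    node_sites.append([str(rng.choice(node_sites[parent]))])
                else:
                    if len(clone_sites) > 1 and rng.random() < cfg.migrate_prob:
                        node_sites.append([str(rng.choice([s for s in clone_sites if s != parent_primary]))])
                    else:
                        node_sites.append([parent_primary])

            for v in range(n_var):
                seq_str = "".join(seqs[v])
                hamm = sum(a != b for a, b in zip(seq_str, germline))
                if hamm != shms[v]:
                    collisions += 1
                cdr3_nt = seq_str[cfg.cdr3_start : cfg.cdr3_start + cfg.cdr3_len]
                cdr3_aa = _translate(cdr3_nt)
                p_switch = 1.0 - float(np.exp(-cfg.csr_rate * depths[v]))
                if rng.random() < p_switch:
                    isotype = str(rng.choice(SWITCHED_CHOICES, p=SWITCHED_PROBS))
                else:
                    isotype = "IGHM" if rng.random() < 0.8 else "IGHD"
                v_sites = node_sites[v]
                v_timepoints = sorted({timepoint_of_site[s] for s in v_sites})
                truth_rows.append(
                    {
                        "participant_id": pid,
                        "true_clone_id": clone_truth_id,
                        "variant": v,
                        "sequence_id": f"c{c:04d}v{v:03d}",
                        "parent": parents[v],
                        "depth": depths[v],
                        "true_shm": shms[v],
                        "is_hub": v in hubs,
                        "n_sites": len(v_sites),
                        "n_timepoints": len(v_timepoints),
                        "sites": ",".join(v_sites),
                        "expanded_clone": expanded,
                        "clone_log10_size": log10_pct,
                    }
                )
                base = {
                    "sequence_id": f"c{c:04d}v{v:03d}",
                    "vdj_nt": seq_str,
                    "cdr3_aa": cdr3_aa,
                    "v_call": v_gene,
                    "isotype": isotype,
                    "shm_count": shms[v],
                    "chain": "IGH",
                }
                variant_weight = cfg.hub_umi_weight if v in hubs else 1.0
                for s in v_sites:
                    emitted[sample_of_site[s]].append((c, log10_pct, variant_weight, base))

        # UMI allocation: a clone's abundance in a sample is drawn from its
        # size component (with per-site jitter) and shared among the clone's
        # variants present there (hubs over-represented); each present
        # variant keeps at least one UMI.
        for sample_id, entries in emitted.items():
            if not entries:
                continue
            clone_var_sum: dict[int, float] = {}
            for c, _, vw, _ in entries:
                clone_var_sum[c] = clone_var_sum.get(c, 0.0) + vw
            clone_sample_weight = {
                c: 10.0 ** (lp + rng.normal(0.0, cfg.site_size_jitter_sd))
                for c, lp in sorted({(c, lp) for c, lp, _, _ in entries})
            }
            weights = np.array(
                [clone_sample_weight[c] * vw / clone_var_sum[c] for c, _, vw, _ in entries]
            )
            n_present = len(entries)
            remaining = max(0, cfg.umi_per_sample - n_present)
            extra_umis = rng.multinomial(remaining, weights / weights.sum())
            for (c, _, vw, base), extra_u in zip(entries, extra_umis):
                row = dict(base)
                row["sample_id"] = sample_id
                row["umi_count"] = 1 + int(extra_u)
                record_rows.append(row)

    if not record_rows:
        raise ValueError("configuration produced zero sequences")
    if collisions:
        logger.info("%d variants had back-mutation collisions (true SHM != Hamming)", collisions)

    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    df = pd.DataFrame(record_rows)
    df["pgen"] = np.nan
    for col in ("participant_id", "site", "timepoint"):
        df[col] = df["sample_id"].map(meta[col])
    df = df[
        [
            "sequence_id",
            "participant_id",
            "sample_id",
            "site",
            "timepoint",
            "chain",
            "vdj_nt",
            "cdr3_aa",
            "v_call",
            "isotype",
            "umi_count",
            "shm_count",
            "pgen",
        ]
    ]
    truth = pd.DataFrame(truth_rows)
    return Repertoire(df, meta), truth


def downsample(rep: Repertoire, fraction: float | None = None, depth: int | None = None, seed=0) -> Repertoire:
    """UMI-weighted downsampling without replacement, per sample.

    Each sample's UMIs are subsampled to ``floor(fraction x total)`` (or to
    ``depth``); record UMI counts are reduced consistently (multivariate
    hypergeometric) and records left with zero UMIs are dropped.
    """
    if (fraction is None) == (depth is None):
        raise ValueError("give exactly one of fraction / depth")
    if fraction is not None and not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    pieces = []
    for sample_id in rep.samples:
        sub = rep.sample(sample_id)
        if sub.empty:
            continue
        total = int(sub["umi_count"].sum())
        target = int(np.floor(fraction * total)) if fraction is not None else int(depth)
        if target > total:
            raise ValueError(f"depth {target} exceeds sample total {total}")
        counts = sub["umi_count"].to_numpy(dtype=np.int64)
        new_counts = rng.multivariate_hypergeometric(counts, target)
        kept = sub.copy()
        kept["umi_count"] = new_counts
        pieces.append(kept[kept["umi_count"] > 0])
    out = pd.concat(pieces, ignore_index=True)
    return Repertoire(out, rep.metadata.reset_index())


_AA = "ACDEFGHIKLMNPQRSTVWY"


def synthetic_reference_db(
    seed: int = 0,
    composition: dict | None = None,
    n_animal: int = 120,
    n_fusion: int = 60,
    n_duplicates: int = 25,
) -> pd.DataFrame:
    """A *synthetic* stand-in for a curated reference antibody table.

    Random CDR3 amino-acid sequences with the retained per-antigen-source
    composition of the curated database (total 5,800 after exclusions), plus
    animal-derived and synthetic-fusion rows and exact duplicates that the
    loader must exclude/deduplicate. The sequences are random, not real
    antibodies.
    """
    comp = dict(composition or REFERENCE_DB_COMPOSITION)
    rng = np.random.default_rng(seed)
    seen = set()

    def _cdr3():
        while True:
            length = int(rng.integers(8, 21))
            s = "C" + "".join(rng.choice(list(_AA), size=length)) + "W"
            if s not in seen:
                seen.add(s)
                return s

    rows = []
    for source, n in comp.items():
        for _ in range(n):
            rows.append(
                {
                    "cdr3_aa": _cdr3(),
                    "antigen_source": source,
                    "species": "human",
                    "entry_type": "antibody",
                    "provenance": "synthetic",
                }
            )
    sources = list(comp)
    for _ in range(n_animal):
        rows.append(
            {
                "cdr3_aa": _cdr3(),
                "antigen_source": str(rng.choice(sources)),
                "species": "mouse",
                "entry_type": "antibody",
                "provenance": "synthetic",
            }
        )
    for _ in range(n_fusion):
        rows.append(
            {
                "cdr3_aa": _cdr3(),
                "antigen_source": str(rng.choice(sources)),
                "species": "human",
                "entry_type": "synthetic_fusion",
                "provenance": "synthetic",
            }
        )
    df = pd.DataFrame(rows)
    if n_duplicates:
        retained = df[(df["species"] == "human") & (df["entry_type"] == "antibody")]
        dup_idx = rng.choice(retained.index, size=n_duplicates, replace=False)
        df = pd.concat([df, df.loc[dup_idx]], ignore_index=True)
    return df.sample(frac=1.0, random_state=int(rng.integers(2**31))).reset_index(drop=True)
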