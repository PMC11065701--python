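"""Fuzzy CDR3 screening against a reference anti-pathogen antibody database.

Tumor CDR3 amino-acid sequences are screened against a curated table of
antibodies with known viral/bacterial specificity to check that clone classes
and high-centrality variants are not enriched for established systemic
(non-tumor) responses. A database entry matches a query iff the two CDR3s
have equal length and Hamming distance at most ``max_mismatch`` (default 3
amino-acid substitutions). Entries flagged as synthetic fusion proteins or
animal-derived are excluded at load time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import cross_hamming
from .io import AA_ALPHABET

logger = logging.getLogger("bcrnet")

EXCLUDED_ENTRY_TYPES = ("synthetic_fusion",)


@dataclass
class ReferenceAntibodyDB:
    """Retained reference entries plus load accounting."""

    entries: pd.DataFrame  # columns: cdr3_aa, antigen_source, provenance
    n_excluded: int = 0
    n_malformed: int = 0
    n_deduplicated: int = 0
    _by_length: dict = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.entries)

    def counts_by_source(self) -> pd.Series:
        return self.entries["antigen_source"].value_counts()

    def by_length(self, length: int):
        """(encoded uint8 matrix, row indices) of entries with this CDR3 length."""
        if length not in self._by_length:
            sub = self.entries[self.entries["cdr3_aa"].str.len() == length]
            if sub.empty:
                self._by_length[length] = (None, np.array([], dtype=int))
            else:
                mat = np.frombuffer(
                    "".join(sub["cdr3_aa"]).encode("ascii"), dtype=np.uint8
                ).reshape(len(sub), length)
                self._by_length[length] = (mat, sub.index.to_numpy())
        return self._by_length[length]


def load_reference_db(
    table,
    species_column: str = "species",
    type_column: str = "entry_type",
) -> ReferenceAntibodyDB:
    """Load and filter a reference antibody table.

    ``table`` is a TSV path or DataFrame with ``cdr3_aa``, ``antigen_source``
    and species / entry-type columns. Entries flagged as synthetic fusion
    proteins or of non-human origin are excluded; malformed CDR3s (empty or
    non-amino-acid characters) are dropped and counted; exact
    (cdr3, source) duplicates are deduplicated and counted.
    """
    if isinstance(table, pd.DataFrame):
        df = table.copy()
    else:
        df = pd.read_csv(table, sep="\t", dtype=str)
    if "cdr3_aa" not in df.columns or "antigen_source" not in df.columns:
        raise ValueError("reference table needs cdr3_aa and antigen_source columns")

    df["cdr3_aa"] = df["cdr3_aa"].fillna("").str.upper().str.strip()
    n0 = len(df)
    wellformed = (df["cdr3_aa"] != "") & df["cdr3_aa"].map(lambda s: set(s) <= AA_ALPHABET)
    df = df[wellformed]
    n_malformed = n0 - len(df)
    if n_malformed:
        logger.warning("dropped %d malformed reference rows", n_malformed)

    n1 = len(df)
    if species_column in df.columns:
        df = df[df[species_column].fillna("human").str.lower().isin(["human", "homo sapiens"])]
    if type_column in df.columns:
        df = df[~df[type_column].fillna("").str.lower().isin(EXCLUDED_ENTRY_TYPES)]
    n_excluded = n1 - len(df)

    n2 = len(df)
    df = df.drop_duplicates(subset=["cdr3_aa", "antigen_source"])
    n_dedup = n2 - len(df)
    if n_dedup:
        logger.info("deduplicated %d reference rows", n_dedup)

    if "provenance" not in df.columns:
        df["provenance"] = ""
    entries = df[["cdr3_aa", "antigen_source", "provenance"]].reset_index(drop=True)
    return ReferenceAntibodyDB(
        entries=entries,
        n_excluded=n_excluded,
        n_malformed=n_malformed,
        n_deduplicated=n_dedup,
    )


def fuzzy_match_cdr3(query_cdr3: str, db: ReferenceAntibodyDB, max_mismatch: int = 3) -> pd.DataFrame:
    """Database entries matching one query CDR3 (equal length, <= max_mismatch).

    Returns the matching entries with a ``mismatches`` column. Matching is
    substitution-only; increasing ``max_mismatch`` never removes matches.
    """
    if not query_cdr3:
        raise ValueError("empty query CDR3")
    query = query_cdr3.upper()
    mat, index = db.by_length(len(query))
    if mat is None:
        return db.entries.iloc[[]].assign(mismatches=pd.Series(dtype=int))
    q = np.frombuffer(query.encode("ascii"), dtype=np.uint8)
    mism = (mat != q).sum(axis=1)
    hit = mism <= max_mismatch
    out = db.entries.loc[index[hit]].copy()
    out["mismatches"] = mism[hit].astype(int)
    return out.reset_index(drop=True)


def screen_cdr3s(queries, db: ReferenceAntibodyDB, max_mismatch: int = 3) -> np.ndarray:
    """Boolean per query: does any DB entry match (vectorized batch screen)."""
    queries = [str(q).upper() for q in queries]
    matched = np.zeros(len(queries), dtype=bool)
    by_len: dict[int, list[int]] = {}
    for i, q in enumerate(queries):
        by_len.setdefault(len(q), []).append(i)
    for length, idxs in by_len.items():
        mat, _ = db.by_length(length)
        if mat is None or length == 0:
            continue
        uniq = sorted({queries[i] for i in idxs})
        hits = (cross_hamming(uniq, ["".join(map(chr, row)) for row in mat]) <= max_mismatch).any(axis=1)
        hit_map = dict(zip(uniq, hits))
        for i in idxs:
            matched[i] = bool(hit_map[queries[i]])
    return matched


def match_enrichment(
    records: pd.DataFrame,
    db: ReferenceAntibodyDB,
    grouping: str = "clone_class",
    max_mismatch: int = 3,
) -> pd.DataFrame:
    """Per-sample, per-group proportion of records with at least one DB match.

    ``grouping`` names a column of ``records`` (e.g. ``clone_class`` or a
    degree bin). Empty groups report NaN. Group comparison is left to
    standard statistical tests.
    """
    if grouping not in records.columns:
        raise ValueError(f"records lack grouping column {grouping!r}")
    work = records.copy()
    work["_matched"] = screen_cdr3s(work["cdr3_aa"], db, max_mismatch=max_mismatch)
    out = (
        work.groupby(["sample_id", grouping], dropna=False, observed=True)["_matched"]
        .agg(matched_proportion="mean", n="size")
        .reset_index()
    )
    return out
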