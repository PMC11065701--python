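"""Repertoire data model and I/O.

A repertoire is a table of unique receptor sequences, one row per unique
rearrangement per sample, with UMI counts as the abundance unit, plus a sample
metadata table (participant, anatomical site, therapy timepoint). Input is an
AIRR Rearrangement-style TSV; the column mapping is configurable so both AIRR
dialect names (``sequence``, ``junction_aa``, ``duplicate_count``, ``c_call``)
and already-canonical names are accepted.

Records failing basic invariants (zero UMIs, non-ACGTN nucleotides, stop codons
in the CDR3, missing sample metadata) are dropped and counted in a
:class:`LoadReport`; unknown isotype strings are kept with ``isotype='unknown'``
and a warning.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("bcrnet")

CHAINS = ("IGH", "TRA", "TRB")

ISOTYPES = (
    "IGHM",
    "IGHD",
    "IGHG1",
    "IGHG2",
    "IGHG3",
    "IGHG4",
    "IGHA1",
    "IGHA2",
    "IGHE",
)
UNSWITCHED_ISOTYPES = ("IGHM", "IGHD")
SWITCHED_ISOTYPES = tuple(i for i in ISOTYPES if i not in UNSWITCHED_ISOTYPES)

NT_ALPHABET = set("ACGTN")
AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

#: canonical column -> default AIRR Rearrangement column
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "sequence_id": "sequence_id",
    "sample_id": "sample_id",
    "vdj_nt": "sequence",
    "cdr3_aa": "junction_aa",
    "v_call": "v_call",
    "umi_count": "duplicate_count",
    "isotype": "c_call",
    "chain": "locus",
    "shm_count": "shm_count",
    "pgen": "pgen",
}

REQUIRED_CANONICAL = ("sequence_id", "sample_id", "vdj_nt", "cdr3_aa", "v_call", "umi_count")

CANONICAL_COLUMNS = (
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
)


@dataclass
class ReceptorRecord:
    """One observed unique receptor sequence with abundance and annotations."""

    sequence_id: str
    participant_id: str
    sample_id: str
    site: str
    timepoint: int | None
    chain: str
    vdj_nt: str
    cdr3_aa: str
    v_call: str
    isotype: str | None
    umi_count: int
    shm_count: int | None = None
    pgen: float | None = None


@dataclass
class LoadReport:
    """Counts of rows read, kept and dropped (by reason) during loading."""

    n_read: int = 0
    n_kept: int = 0
    dropped: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)

    @property
    def drop_count(self) -> int:
        return int(sum(self.dropped.values()))

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


class Repertoire:
    """A validated repertoire table plus per-sample metadata.

    Attributes
    ----------
    df : pandas.DataFrame
        One row per unique sequence per sample, canonical columns
        (metadata columns merged in for convenience).
    metadata : pandas.DataFrame
        Indexed by ``sample_id`` with ``participant_id``, ``site``,
        ``timepoint`` columns.
    load_report : LoadReport or None
    """

    def __init__(self, df: pd.DataFrame, metadata: pd.DataFrame, load_report: LoadReport | None = None):
        self.df = df.reset_index(drop=True)
        if metadata.index.name != "sample_id":
            metadata = metadata.set_index("sample_id")
        self.metadata = metadata
        self.load_report = load_report

    def __len__(self) -> int:
        return len(self.df)

    @property
    def samples(self) -> list[str]:
        return list(self.metadata.index)

    @property
    def participants(self) -> list[str]:
        return sorted(self.metadata["participant_id"].unique())

    def sample(self, sample_id: str) -> pd.DataFrame:
        return self.df[self.df["sample_id"] == sample_id]

    def for_participant(self, participant_id: str) -> pd.DataFrame:
        return self.df[self.df["participant_id"] == participant_id]

    def unique_vdj(self, sample_id: str) -> np.ndarray:
        return self.sample(sample_id)["vdj_nt"].unique()

    def records(self) -> Iterable[ReceptorRecord]:
        for row in self.df.itertuples(index=False):
            yield ReceptorRecord(
                sequence_id=row.sequence_id,
                participant_id=row.participant_id,
                sample_id=row.sample_id,
                site=row.site,
                timepoint=None if pd.isna(row.timepoint) else int(row.timepoint),
                chain=row.chain,
                vdj_nt=row.vdj_nt,
                cdr3_aa=row.cdr3_aa,
                v_call=row.v_call,
                isotype=None if pd.isna(row.isotype) else row.isotype,
                umi_count=int(row.umi_count),
                shm_count=None if pd.isna(row.shm_count) else int(row.shm_count),
                pgen=None if pd.isna(row.pgen) else float(row.pgen),
            )


def normalize_v_call(v_call: str) -> str:
    """Strip allele suffixes and secondary calls: ``IGHV1-69*01,IGHV1-69*02`` -> ``IGHV1-69``."""
    if not isinstance(v_call, str):
        return ""
    return v_call.split(",")[0].split("*")[0].strip()


def _normalize_isotype(value, chain: str, report: LoadReport):
    if chain != "IGH":
        return None
    if value is None or (isinstance(value, float) and np.isnan(value)) or value == "":
        return "unknown"
    val = str(value).upper().replace("IGA", "IGHA").replace("IGG", "IGHG")
    if val in ("IGM", "IGD", "IGE"):
        val = "IGH" + val[2:]
    if val in ISOTYPES:
        return val
    msg = f"unknown isotype {value!r} kept as 'unknown'"
    if msg not in report.warnings:
        report.warnings.append(msg)
        logger.warning(msg)
    return "unknown"


def _infer_chain(value) -> str:
    if isinstance(value, str) and value.upper() in CHAINS:
        return value.upper()
    return "IGH"


def read_repertoire(
    path,
    metadata,
    columns: Mapping[str, str] | None = None,
) -> Repertoire:
    """Read an AIRR-style rearrangement TSV into a validated :class:`Repertoire`.

    Parameters
    ----------
    path : str or file-like
        TSV with a header row. Required columns (after mapping):
        sequence_id, sample_id, sequence, junction_aa, v_call, duplicate_count.
    metadata : str, file-like or DataFrame
        Sample metadata TSV/frame with sample_id, participant_id, site,
        timepoint columns.
    columns : mapping, optional
        Overrides for :data:`DEFAULT_COLUMN_MAP` (canonical -> file column).

    Rows failing invariants are dropped and counted in ``.load_report``.
    Raises ``ValueError`` on an empty file or a missing required column.
    """
    colmap = dict(DEFAULT_COLUMN_MAP)
    if columns:
        colmap.update(columns)

    try:
        raw = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty repertoire file: {path}") from exc
    if raw.empty:
        raise ValueError(f"repertoire file has no rows: {path}")

    if isinstance(metadata, pd.DataFrame):
        meta = metadata.copy()
    else:
        meta = pd.read_csv(metadata, sep="\t", dtype={"sample_id": str, "participant_id": str, "site": str})
    if "timepoint" not in meta.columns:
        meta["timepoint"] = np.nan
    meta["timepoint"] = pd.to_numeric(meta["timepoint"], errors="coerce")
    if meta.index.name != "sample_id":
        meta = meta.set_index("sample_id")

    # accept canonical names directly when the mapped name is absent
    resolved = {}
    for canon, filecol in colmap.items():
        if filecol in raw.columns:
            resolved[canon] = filecol
        elif canon in raw.columns:
            resolved[canon] = canon
    missing = [c for c in REQUIRED_CANONICAL if c not in resolved]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")

    df = pd.DataFrame({canon: raw[fc] for canon, fc in resolved.items()})
    report = LoadReport(n_read=len(df))

    df["umi_count"] = pd.to_numeric(df["umi_count"], errors="coerce")
    if "shm_count" in df.columns:
        df["shm_count"] = pd.to_numeric(df["shm_count"], errors="coerce")
    else:
        df["shm_count"] = np.nan
    if "pgen" in df.columns:
        df["pgen"] = pd.to_numeric(df["pgen"], errors="coerce")
    else:
        df["pgen"] = np.nan

    df["chain"] = df["chain"].map(_infer_chain) if "chain" in df.columns else "IGH"
    df["v_call"] = df["v_call"].map(normalize_v_call)
    df["vdj_nt"] = df["vdj_nt"].fillna("").str.upper()
    df["cdr3_aa"] = df["cdr3_aa"].fillna("").str.upper()

    def _drop(mask: pd.Series, reason: str) -> pd.DataFrame:
        n = int(mask.sum())
        if n:
            report.dropped[reason] = report.dropped.get(reason, 0) + n
        return df[~mask]

    df = _drop(~(df["umi_count"] >= 1) | (df["umi_count"] % 1 != 0), "umi_count_lt_1")
    df = _drop(df["vdj_nt"] == "", "empty_vdj")
    df = _drop(~df["vdj_nt"].map(lambda s: set(s) <= NT_ALPHABET), "bad_nt_alphabet")
    df = _drop(df["cdr3_aa"].str.contains(r"\*", regex=True), "stop_codon_cdr3")
    df = _drop(~df["cdr3_aa"].map(lambda s: set(s) <= AA_ALPHABET), "bad_aa_alphabet")
    df = _drop(~df["sample_id"].isin(meta.index), "no_sample_metadata")
    df = _drop(df["v_call"] == "", "empty_v_call")

    iso_col = df.get("isotype", pd.Series("", index=df.index))
    df = df.assign(
        isotype=[_normalize_isotype(v, c, report) for v, c in zip(iso_col, df["chain"])]
    )
    df["umi_count"] = df["umi_count"].astype(int)

    for col in ("participant_id", "site", "timepoint"):
        df[col] = df["sample_id"].map(meta[col])

    report.n_kept = len(df)
    df = df[list(CANONICAL_COLUMNS)]
    return Repertoire(df, meta, load_report=report)


def write_repertoire(rep: Repertoire, path, metadata_path=None, columns: Mapping[str, str] | None = None) -> None:
    """Write the repertoire back out in the same AIRR TSV dialect."""
    colmap = dict(DEFAULT_COLUMN_MAP)
    if columns:
        colmap.update(columns)
    out = rep.df.copy()
    out = out.drop(columns=["participant_id", "site", "timepoint"])
    out = out.rename(columns={c: colmap.get(c, c) for c in out.columns})
    out.to_csv(path, sep="\t", index=False)
    if metadata_path is not None:
        rep.metadata.reset_index().to_csv(metadata_path, sep="\t", index=False)


def collapse_identical(df: pd.DataFrame) -> pd.DataFrame:
    """Merge records with identical ``vdj_nt`` within each (sample, chain).

    UMI counts are summed; all other annotations are taken from the
    highest-abundance member. Total UMI count is conserved.
    """
    if df.empty:
        return df.copy()

    def _collapse_group(g: pd.DataFrame) -> pd.Series:
        top = g.loc[g["umi_count"].idxmax()].copy()
        top["umi_count"] = int(g["umi_count"].sum())
        return top

    grouped = (
        df.groupby(["sample_id", "chain", "vdj_nt"], sort=False, group_keys=False)
        .apply(_collapse_group, include_groups=False)
        .reset_index()
    )
    return grouped[[c for c in df.columns]].reset_index(drop=True)
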