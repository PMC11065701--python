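"""Shared builders for hand-made record tables."""

import numpy as np
import pandas as pd


def make_records(rows, participant="P1"):
    """Build a canonical record table from compact row dicts."""
    defaults = {
        "participant_id": participant,
        "sample_id": "s1",
        "site": "lymph_node",
        "timepoint": 0,
        "chain": "IGH",
        "cdr3_aa": "CARDW",
        "v_call": "IGHV1-1",
        "isotype": "IGHM",
        "umi_count": 1,
        "shm_count": 0,
        "pgen": np.nan,
    }
    out = []
    for i, row in enumerate(rows):
        rec = dict(defaults)
        rec["sequence_id"] = f"seq{i}"
        rec.setdefault("vdj_nt", "ACGT" * 25)
        rec.update(row)
        out.append(rec)
    return pd.DataFrame(out)
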