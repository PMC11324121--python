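"""Glue from raw records and echo exams to model-ready arrays."""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import ecg_io
from .patching import patchify


def build_cohort(records, echoes, ratios=(0.7, 0.15, 0.15), seed: int = 0
                 ) -> pd.DataFrame:
    """Pair, label and split: the full cohort-table construction."""
    table = ecg_io.pair_exams(records, echoes)
    table = ecg_io.split_cohort(table, ratios=ratios, seed=seed)
    ecg_io.validate_cohort(table)
    return table


def patch_stack(records, normalize: bool = True) -> np.ndarray:
    """Normalize and patchify records into an (n, 240, 250) float32 stack."""
    out = np.empty((len(records), 240, 250), dtype=np.float32)
    for i, rec in enumerate(records):
        if normalize:
            rec = ecg_io.normalize(rec)
        out[i] = patchify(rec).patches
    return out


def split_arrays(records, table: pd.DataFrame, split: str,
                 normalize: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Patch stack and LVSD label vector for one split of a cohort."""
    by_id = {r.record_id: r for r in records}
    rows = table[table["split"] == split]
    recs = [by_id[rid] for rid in rows["record_id"]]
    labels = rows["lvsd_label"].to_numpy(dtype=np.float64)
    return patch_stack(recs, normalize=normalize), labels
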