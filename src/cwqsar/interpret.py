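"""Mechanistic interpretation: enhancing vs reducing promoters.

Correlation weights from several independent Monte-Carlo probes are
compared attribute by attribute.  An attribute whose weight is strictly
positive in every probe is a promoter of endpoint increase; strictly
negative in every probe, a promoter of decrease; anything else (including
an exact zero, which asserts no sign) is inconsistent and excluded from
mechanistic reading.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .registry import AttributeRegistry
from .smiles import AttributeKey


def classify_promoters(
    probe_weights: Sequence[Mapping[AttributeKey, float]],
    registry: AttributeRegistry,
    defect_table: Mapping[AttributeKey, float] | None = None,
) -> pd.DataFrame:
    """One row per active attribute with per-probe CWs and its sign class.

    Rows are sorted by |mean CW| descending within each class
    (increase, decrease, inconsistent).
    """
    if len(probe_weights) < 2:
        raise ValueError("need at least 2 probes to classify promoter consistency")
    active = set(registry.active_keys)
    for i, table in enumerate(probe_weights):
        if set(table) != active:
            raise ValueError(f"probe {i} covers a different attribute set than the registry")
    rows = []
    for key in registry.active_keys:
        cws = np.array([float(t[key]) for t in probe_weights])
        if np.all(cws > 0):
            cls = "increase"
        elif np.all(cws < 0):
            cls = "decrease"
        else:
            cls = "inconsistent"
        rec = registry.records[key]
        row = {
            "code": key.code,
            "kind": key.kind,
            **{f"cw_probe_{i + 1}": cw for i, cw in enumerate(cws)},
            "mean_cw": float(cws.mean()),
            "n_trn": rec.presence["TRN"],
            "n_itrn": rec.presence["iTRN"],
            "n_cal": rec.presence["CAL"],
            "n_val": rec.presence["VAL"],
            "defect": float(defect_table.get(key, float("nan"))) if defect_table else float("nan"),
            "class": cls,
        }
        rows.append(row)
    df = pd.DataFrame(rows)
    rank = {"increase": 0, "decrease": 1, "inconsistent": 2}
    df["_rank"] = df["class"].map(rank)
    df["_abs"] = df["mean_cw"].abs()
    df = df.sort_values(["_rank", "_abs"], ascending=[True, False]).drop(columns=["_rank", "_abs"])
    return df.reset_index(drop=True)
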