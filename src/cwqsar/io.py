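"""Compound tables, activity conversion and four-way split assignment.

Compound tables are plain CSV with an ``id`` column, a ``smiles`` column and
exactly one activity column out of ``pic50``, ``ic50_M`` or ``ic50_uM``
(IC50 columns are converted to pIC50 on read).  Split files are CSV
``id,subset`` with subset in {TRN, iTRN, CAL, VAL}; published splits can be
replayed by supplying such a file, random assignment is the fallback.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .registry import SUBSETS

logger = logging.getLogger("cwqsar")

_ACTIVITY_COLUMNS = ("pic50", "ic50_M", "ic50_uM")


def convert_ic50_to_pic50(ic50: float) -> float:
    """−log10 of a molar IC50."""
    if not (ic50 > 0):
        raise ValueError(f"IC50 must be a positive concentration, got {ic50!r}")
    return -math.log10(ic50)


def read_dataset(path) -> pd.DataFrame:
    """Read a compound table; returns columns ``id``, ``smiles``, ``pic50``.

    Rows with a missing/duplicate id, empty SMILES or an unparsable
    activity are rejected with a logged reason rather than aborting the
    load.
    """
    df = pd.read_csv(path, dtype={"id": str, "smiles": str})
    cols = set(df.columns)
    if "id" not in cols or "smiles" not in cols:
        raise ValueError(f"{path}: table must have 'id' and 'smiles' columns")
    activity = [c for c in _ACTIVITY_COLUMNS if c in cols]
    if len(activity) != 1:
        raise ValueError(
            f"{path}: need exactly one activity column out of {_ACTIVITY_COLUMNS}, found {activity}"
        )
    act = activity[0]
    rows = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        ident = row["id"]
        if not isinstance(ident, str) or not ident.strip():
            logger.warning("row %d rejected: missing id", i)
            continue
        if ident in seen:
            logger.warning("row %d rejected: duplicate id %r", i, ident)
            continue
        smiles = row["smiles"]
        if not isinstance(smiles, str) or not smiles.strip():
            logger.warning("row %d (%s) rejected: empty SMILES", i, ident)
            continue
        try:
            value = float(row[act])
            if not math.isfinite(value):
                raise ValueError("not finite")
            if act == "ic50_M":
                value = convert_ic50_to_pic50(value)
            elif act == "ic50_uM":
                value = convert_ic50_to_pic50(value * 1e-6)
        except (TypeError, ValueError) as exc:
            logger.warning("row %d (%s) rejected: bad activity %r (%s)", i, ident, row[act], exc)
            continue
        seen.add(ident)
        rows.append({"id": ident, "smiles": smiles.strip(), "pic50": round(value, 4)})
    return pd.DataFrame(rows, columns=["id", "smiles", "pic50"])


def write_dataset(df: pd.DataFrame, path) -> None:
    out = df[["id", "smiles", "pic50"]].copy()
    out["pic50"] = out["pic50"].map(lambda v: f"{v:.6f}")
    out.to_csv(path, index=False)


def assign_splits(
    ids: Sequence[str],
    proportions: Sequence[float] = (0.27, 0.27, 0.23, 0.23),
    seed: int = 0,
) -> dict[str, str]:
    """Random four-way partition into TRN / iTRN / CAL / VAL.

    Subset sizes are the largest-remainder rounding of proportion × n, so
    each is within one of its target and they sum to n.  Deterministic for
    a fixed seed.
    """
    n = len(ids)
    if n < 8:
        raise ValueError("need at least 8 compounds to populate four subsets")
    if len(proportions) != 4:
        raise ValueError("exactly four proportions required")
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    raw = [p * n for p in proportions]
    sizes = [int(math.floor(r)) for r in raw]
    remainders = sorted(range(4), key=lambda i: raw[i] - sizes[i], reverse=True)
    for i in range(n - sum(sizes)):
        sizes[remainders[i % 4]] += 1
    if min(sizes) == 0:
        raise ValueError("too few compounds: a subset would be empty")
    rng = np.random.default_rng(seed)
    shuffled = list(rng.permutation(np.asarray(ids, dtype=object)))
    splits: dict[str, str] = {}
    start = 0
    for label, size in zip(SUBSETS, sizes):
        for ident in shuffled[start : start + size]:
            splits[str(ident)] = label
        start += size
    return splits


def read_split_file(path) -> dict[str, str]:
    """Read an ``id,subset`` CSV; validates labels."""
    df = pd.read_csv(path, dtype=str)
    if "id" not in df.columns or "subset" not in df.columns:
        raise ValueError(f"{path}: split file must have 'id' and 'subset' columns")
    splits: dict[str, str] = {}
    for _, row in df.iterrows():
        if row["subset"] not in SUBSETS:
            raise ValueError(f"{path}: unknown subset label {row['subset']!r}")
        if row["id"] in splits:
            raise ValueError(f"{path}: id {row['id']!r} assigned twice")
        splits[row["id"]] = row["subset"]
    return splits


def write_split_file(splits: Mapping[str, str], path) -> None:
    pd.DataFrame(
        {"id": list(splits), "subset": [splits[i] for i in splits]}
    ).to_csv(path, index=False)


def read_config(path) -> dict[str, str]:
    """Flat ``key=value`` config text; '#' starts a comment."""
    out: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}: malformed config line {raw!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out
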