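"""Attribute registry: occurrence statistics, rarity threshold, DCW.

The registry is the bridge between featurization and optimization.  It
records, for every attribute ever seen in the dataset, how many compounds
of each subset contain it (presence counts) and how many times it occurs in
total per subset (occurrence counts).  An attribute is *active* when it is
present in at least ``threshold`` compounds of the visible model-building
subsets (training ∪ invisible training); inactive attributes are blocked —
their correlation weight is pinned to zero and they never contribute to any
descriptor value.

The descriptor of correlation weights (DCW) of a compound is the sum of the
correlation weights of its active attributes, counted with multiplicity,
and splits additively into a SMILES part and a graph part.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .features import Compound, is_graph_kind
from .smiles import AttributeKey

SUBSETS = ("TRN", "iTRN", "CAL", "VAL")


@dataclass
class AttributeRecord:
    key: AttributeKey
    presence: dict[str, int] = field(default_factory=lambda: {s: 0 for s in SUBSETS})
    occurrences: dict[str, int] = field(default_factory=lambda: {s: 0 for s in SUBSETS})
    active: bool = False
    correlation_weight: float = 0.0


@dataclass
class DescriptorValue:
    """Hybrid descriptor value with its additive split."""

    dcw: float
    smiles_part: float
    graph_part: float


class AttributeRegistry:
    """Per-attribute statistics and correlation weights for one dataset/split."""

    def __init__(self, threshold: int = 1):
        if threshold < 1:
            raise ValueError("threshold must be >= 1")
        self.threshold = threshold
        self.records: dict[AttributeKey, AttributeRecord] = {}

    @classmethod
    def build(
        cls,
        compounds: Iterable[Compound],
        splits: Mapping[str, str],
        threshold: int = 1,
    ) -> "AttributeRegistry":
        """Accumulate presence/occurrence counts and apply the rarity threshold.

        ``splits`` maps compound id to one of TRN, iTRN, CAL, VAL.  Activity
        is decided on TRN ∪ iTRN presence alone, so attributes confined to
        the calibration or validation sets stay blocked regardless of T.
        """
        reg = cls(threshold)
        seen_any = False
        for comp in compounds:
            subset = splits.get(comp.id)
            if subset is None:
                raise KeyError(f"compound {comp.id!r} has no split assignment")
            if subset not in SUBSETS:
                raise ValueError(f"unknown subset label {subset!r} for compound {comp.id!r}")
            if subset in ("TRN", "iTRN"):
                seen_any = True
            if not comp.attributes:
                comp.featurize()
            for key, count in comp.attributes.items():
                rec = reg.records.get(key)
                if rec is None:
                    rec = reg.records[key] = AttributeRecord(key)
                rec.presence[subset] += 1
                rec.occurrences[subset] += count
        if not seen_any:
            raise ValueError("training subsets are empty; cannot build a registry")
        for rec in reg.records.values():
            rec.active = rec.presence["TRN"] + rec.presence["iTRN"] >= threshold
            if not rec.active:
                rec.correlation_weight = 0.0
        return reg

    @property
    def active_keys(self) -> list[AttributeKey]:
        return [k for k, r in self.records.items() if r.active]

    def set_weights(self, weights: Mapping[AttributeKey, float]) -> None:
        for key, w in weights.items():
            rec = self.records[key]
            if not rec.active:
                raise ValueError(f"attribute {key.code!r} is blocked; weight is pinned to 0")
            rec.correlation_weight = float(w)

    def weights(self) -> dict[AttributeKey, float]:
        return {k: r.correlation_weight for k, r in self.records.items() if r.active}

    def compute_dcw(self, compound: Compound) -> DescriptorValue:
        """Hybrid DCW of one compound under the current weights.

        Attributes unknown to the registry (new chemistry at prediction
        time) contribute zero; blocked attributes are zero by construction.
        """
        if not compound.attributes:
            compound.featurize()
        smiles_part = 0.0
        graph_part = 0.0
        for key, count in compound.attributes.items():
            rec = self.records.get(key)
            if rec is None or not rec.active:
                continue
            contrib = count * rec.correlation_weight
            if is_graph_kind(key.kind):
                graph_part += contrib
            else:
                smiles_part += contrib
        return DescriptorValue(smiles_part + graph_part, smiles_part, graph_part)

    def count_matrix(self, compounds: list[Compound]) -> tuple[np.ndarray, list[AttributeKey]]:
        """Dense (n_compounds × n_active) occurrence-count matrix.

        The optimizer works on this matrix: the DCW vector is ``X @ w``.
        """
        keys = self.active_keys
        index = {k: j for j, k in enumerate(keys)}
        X = np.zeros((len(compounds), len(keys)))
        for i, comp in enumerate(compounds):
            if not comp.attributes:
                comp.featurize()
            for key, count in comp.attributes.items():
                j = index.get(key)
                if j is not None:
                    X[i, j] = count
        return X, keys

    def to_frame(self) -> pd.DataFrame:
        """CW table: one row per attribute with counts, activity and weight."""
        rows = []
        for key, rec in sorted(self.records.items()):
            rows.append(
                {
                    "code": key.code,
                    "kind": key.kind,
                    "active": rec.active,
                    "cw": rec.correlation_weight,
                    "n_trn": rec.presence["TRN"],
                    "n_itrn": rec.presence["iTRN"],
                    "n_cal": rec.presence["CAL"],
                    "n_val": rec.presence["VAL"],
                }
            )
        return pd.DataFrame(rows)

    def write_cw_table(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
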