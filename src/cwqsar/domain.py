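"""Applicability domain via statistical defects of structural attributes.

An attribute's defect measures how differently it is distributed between
the training and calibration sets:

    defect(A) = |P_TRN(A) − P_CAL(A)| / (N_TRN(A) + N_CAL(A))   if A occurs
    defect(A) = 1                                               if A is absent

where P is the fraction of compounds containing the attribute and N the
total occurrence count.  A molecule's defect is the sum over its attributes
(with multiplicity); attributes that are blocked in the registry or never
seen by the model count as absent (defect 1 per occurrence) — this is what
flags genuinely new chemistry.  A compound is outside the applicability
domain when its defect exceeds twice the mean training-set molecular
defect (strictly: equality is still in-domain).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import Compound
from .registry import AttributeRegistry
from .smiles import AttributeKey


def attribute_defect(
    n_trn: int,
    size_trn: int,
    n_cal: int,
    size_cal: int,
    occ_trn: int | None = None,
    occ_cal: int | None = None,
) -> float:
    """Statistical defect of one attribute.

    ``n_*``/``size_*`` give the presence probabilities; ``occ_*`` the
    occurrence totals for the denominator (defaulting to the presence
    counts when not given separately).
    """
    if size_trn <= 0 or size_cal <= 0:
        raise ValueError("subset sizes must be positive")
    if n_trn > size_trn or n_cal > size_cal:
        raise ValueError("presence count exceeds subset size")
    occ_trn = n_trn if occ_trn is None else occ_trn
    occ_cal = n_cal if occ_cal is None else occ_cal
    if occ_trn + occ_cal == 0:
        return 1.0
    p_trn = n_trn / size_trn
    p_cal = n_cal / size_cal
    return abs(p_trn - p_cal) / (occ_trn + occ_cal)


def build_defect_table(registry: AttributeRegistry, size_trn: int, size_cal: int
                       ) -> dict[AttributeKey, float]:
    """Per-attribute defects for every *active* attribute of the registry."""
    table: dict[AttributeKey, float] = {}
    for key, rec in registry.records.items():
        if not rec.active:
            continue
        table[key] = attribute_defect(
            rec.presence["TRN"],
            size_trn,
            rec.presence["CAL"],
            size_cal,
            occ_trn=rec.occurrences["TRN"],
            occ_cal=rec.occurrences["CAL"],
        )
    return table


def molecule_defect(compound: Compound, defect_table: dict[AttributeKey, float]) -> float:
    """Sum of attribute defects over the compound's attributes.

    Occurrences of attributes missing from the defect table (blocked or
    never seen) each contribute the absent-attribute defect of 1.
    """
    if not compound.attributes:
        compound.featurize()
    total = 0.0
    for key, count in compound.attributes.items():
        total += count * defect_table.get(key, 1.0)
    return total


@dataclass
class DomainReport:
    """Per-compound defects, the AD threshold and per-subset coverage."""

    per_compound: pd.DataFrame = field(repr=False)
    mean_trn_defect: float = 0.0
    threshold: float = 0.0

    def coverage(self) -> pd.Series:
        """Fraction of each subset inside the applicability domain."""
        return self.per_compound.groupby("subset", sort=False)["in_domain"].mean()


def domain_report(
    compounds: list[Compound],
    splits: dict[str, str],
    defect_table: dict[AttributeKey, float],
) -> DomainReport:
    """Flag every compound against the 2 × mean-training-defect threshold."""
    rows = []
    for comp in compounds:
        rows.append(
            {
                "id": comp.id,
                "subset": splits[comp.id],
                "defect": molecule_defect(comp, defect_table),
            }
        )
    df = pd.DataFrame(rows)
    trn = df[df["subset"] == "TRN"]
    if trn.empty:
        raise ValueError("training subset is empty; AD threshold undefined")
    mean_trn = float(trn["defect"].mean())
    threshold = 2.0 * mean_trn
    df["threshold"] = threshold
    df["in_domain"] = df["defect"] <= threshold
    return DomainReport(df, mean_trn, threshold)
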