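"""Compound featurization: one attribute multiset per molecule.

Combines the SMILES-string attributes with the hydrogen-suppressed-graph
attributes into a single :class:`collections.Counter` keyed by
:class:`~cwqsar.smiles.AttributeKey`.  The two halves never collide: kinds
are disjoint, which is what lets the descriptor split additively into its
SMILES and graph parts.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .graph import GRAPH_KINDS, build_hsg, graph_attributes
from .smiles import SMILES_KINDS, AttributeKey, smiles_attributes

assert not (SMILES_KINDS & GRAPH_KINDS)


@dataclass
class Compound:
    """One molecule: identifier, verbatim SMILES, activity, attributes."""

    id: str
    smiles: str
    pic50: float | None = None
    attributes: Counter[AttributeKey] = field(default_factory=Counter)

    def featurize(self) -> "Compound":
        self.attributes = featurize(self.smiles)
        return self


def featurize(smiles: str) -> Counter[AttributeKey]:
    """All structural attributes (string + graph) of one SMILES."""
    attrs = smiles_attributes(smiles)
    attrs.update(graph_attributes(build_hsg(smiles)))
    return attrs


def is_graph_kind(kind: str) -> bool:
    return kind in GRAPH_KINDS
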