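"""Hydrogen-suppressed molecular graph (HSG) and its topological invariants.

The HSG is the heavy-atom skeleton read directly off the SMILES token
stream: vertices are atoms in token order, edges come from chain adjacency,
branching and ring-closure pairing.  Bond orders are ignored — double bonds
influence only the string attributes, the graph carries pure topology.

Per-vertex invariants
---------------------
ec0, ec1   Morgan extended connectivity: vertex degree and the sum of the
           neighbours' degrees.
pt2, pt3   number of simple paths of exactly 2 / 3 edges starting at the
           vertex (no repeated vertices).
s2, s3     valence shells: sum of degrees of all vertices at topological
           distance exactly 2 / 3.
nnc        nearest-neighbour code, a three-digit string
           (heavy-neighbour count, carbon neighbours, non-carbon
           neighbours); a carbonyl carbon reads ``321``.

Ring codes cover 5- and 6-membered rings of a minimum cycle basis, tagged
with aromaticity (all member atoms aromatic in the SMILES) and heteroatom
count.  Together with the six sum/absolute-difference combinations of the
(ec, pt, s) pairs these invariants generate the graph half of the hybrid
descriptor.
"""

from __future__ import annotations

from collections import Counter
from typing import NamedTuple

import networkx as nx

from .smiles import AttributeKey, SmilesParseError, _bracket_element, tokenize_smiles

_ORGANIC = {"B", "C", "N", "O", "P", "S", "F", "I", "Cl", "Br", "Si"}
_AROMATIC = set("bcnops")


class RingCode(NamedTuple):
    size: int
    aromatic: bool
    heteroatoms: int


def build_hsg(smiles: str) -> nx.Graph:
    """Parse a SMILES string into its hydrogen-suppressed graph.

    Node attributes: ``element`` (uppercase symbol) and ``aromatic``
    (lowercase organic-subset symbol or lowercase bracket atom).
    Explicit hydrogens (``[H]``, in-bracket H counts) are dropped.
    """
    tokens = tokenize_smiles(smiles)
    g = nx.Graph()
    prev: int | None = None
    stack: list[int | None] = []
    ring_open: dict[str, int] = {}
    pending_bond = False
    idx = 0
    for t in tokens:
        if t == "(":
            stack.append(prev)
        elif t == ")":
            if not stack:
                raise SmilesParseError(f"unbalanced ')' in {smiles!r}")
            prev = stack.pop()
        elif t in "=#-/\\":
            pending_bond = True
        elif t == ".":
            prev = None
        elif t in ("@", "+"):
            pass
        elif t.isdigit() or t.startswith("%"):
            label = t.lstrip("%")
            if prev is None:
                raise SmilesParseError(f"ring closure {t!r} before any atom in {smiles!r}")
            if label in ring_open:
                other = ring_open.pop(label)
                if other == prev:
                    raise SmilesParseError(f"self ring closure {t!r} in {smiles!r}")
                g.add_edge(prev, other)
            else:
                ring_open[label] = prev
            pending_bond = False
        else:
            # atom token
            if t.startswith("["):
                el = _bracket_element(t)
                if el is None:
                    raise SmilesParseError(f"cannot read element from {t!r}")
                aromatic = el.islower()
                element = el.upper()
            else:
                if t not in _ORGANIC and t not in _AROMATIC:
                    raise SmilesParseError(f"unexpected token {t!r} in {smiles!r}")
                aromatic = t in _AROMATIC
                element = t.upper()
            if element == "H":
                pending_bond = False
                continue
            g.add_node(idx, element=element, aromatic=aromatic)
            if prev is not None:
                g.add_edge(prev, idx)
            prev = idx
            idx += 1
            pending_bond = False
    if ring_open:
        raise SmilesParseError(f"unmatched ring-closure label(s) {sorted(ring_open)} in {smiles!r}")
    if pending_bond:
        raise SmilesParseError(f"dangling bond symbol at end of {smiles!r}")
    return g


def morgan_connectivity(g: nx.Graph) -> dict[int, tuple[int, int]]:
    """(ec0, ec1) per vertex: degree and sum of neighbours' degrees."""
    deg = dict(g.degree())
    return {v: (deg[v], sum(deg[u] for u in g.neighbors(v))) for v in g.nodes}


def path_counts(g: nx.Graph, length: int) -> dict[int, int]:
    """Simple-path counts of exactly ``length`` edges starting at each vertex."""
    if length < 1:
        raise ValueError("length must be >= 1")

    def count_from(v: int) -> int:
        total = 0
        stack = [(v, {v}, 0)]
        while stack:
            node, visited, depth = stack.pop()
            if depth == length:
                total += 1
                continue
            for u in g.neighbors(node):
                if u not in visited:
                    stack.append((u, visited | {u}, depth + 1))
        return total

    return {v: count_from(v) for v in g.nodes}


def valence_shells(g: nx.Graph, order: int) -> dict[int, int]:
    """Sum of degrees over vertices at shortest-path distance exactly ``order``."""
    deg = dict(g.degree())
    out: dict[int, int] = {}
    for v in g.nodes:
        layers = nx.single_source_shortest_path_length(g, v, cutoff=order)
        out[v] = sum(deg[u] for u, d in layers.items() if d == order)
    return out


def nearest_neighbor_codes(g: nx.Graph) -> dict[int, str]:
    """Three-digit (total, carbon, non-carbon) neighbour code per vertex."""
    codes: dict[int, str] = {}
    for v in g.nodes:
        nbrs = list(g.neighbors(v))
        if len(nbrs) > 9:
            raise ValueError(f"vertex {v} has {len(nbrs)} neighbours; not chemically possible")
        nc = sum(1 for u in nbrs if g.nodes[u]["element"] == "C")
        codes[v] = f"{len(nbrs)}{nc}{len(nbrs) - nc}"
    return codes


def ring_codes(g: nx.Graph) -> Counter[RingCode]:
    """Codes of 5-/6-membered rings in a minimum cycle basis."""
    codes: Counter[RingCode] = Counter()
    for cycle in nx.minimum_cycle_basis(g):
        if len(cycle) not in (5, 6):
            continue
        aromatic = all(g.nodes[v]["aromatic"] for v in cycle)
        het = sum(1 for v in cycle if g.nodes[v]["element"] != "C")
        codes[RingCode(len(cycle), aromatic, het)] += 1
    return codes


def _vkey(prefix: str, element: str, value: int | str) -> AttributeKey:
    code = f"{prefix}-{element[:4].ljust(4, '.')}{str(value)[:4].ljust(4, '.')}"
    return AttributeKey(prefix, code)


def graph_attributes(g: nx.Graph) -> Counter[AttributeKey]:
    """Full graph-attribute multiset: per-vertex invariant keys, their six
    sum/absolute-difference combinations, and ring codes.

    Keys carry the element symbol and the invariant value, e.g.
    ``PT2-C...3...`` or ``NNC-C...321.``.
    """
    attrs: Counter[AttributeKey] = Counter()
    if g.number_of_nodes() == 0:
        return attrs
    ec = morgan_connectivity(g)
    pt2 = path_counts(g, 2)
    pt3 = path_counts(g, 3)
    s2 = valence_shells(g, 2)
    s3 = valence_shells(g, 3)
    nnc = nearest_neighbor_codes(g)
    for v in g.nodes:
        el = g.nodes[v]["element"]
        e0, e1 = ec[v]
        attrs[_vkey("EC0", el, e0)] += 1
        attrs[_vkey("EC1", el, e1)] += 1
        attrs[_vkey("ECS", el, e0 + e1)] += 1
        attrs[_vkey("ECD", el, abs(e0 - e1))] += 1
        attrs[_vkey("PT2", el, pt2[v])] += 1
        attrs[_vkey("PT3", el, pt3[v])] += 1
        attrs[_vkey("PTS", el, pt2[v] + pt3[v])] += 1
        attrs[_vkey("PTD", el, abs(pt2[v] - pt3[v]))] += 1
        attrs[_vkey("VS2", el, s2[v])] += 1
        attrs[_vkey("VS3", el, s3[v])] += 1
        attrs[_vkey("VSS", el, s2[v] + s3[v])] += 1
        attrs[_vkey("VSD", el, abs(s2[v] - s3[v]))] += 1
        attrs[_vkey("NNC", el, nnc[v])] += 1
    for rc, count in ring_codes(g).items():
        kind = f"C{rc.size}"
        flag = "A" if rc.aromatic else "N"
        code = f"C{rc.size}...{flag}H.{rc.heteroatoms}..."
        attrs[AttributeKey(kind, code)] += count
    return attrs


GRAPH_KINDS = frozenset(
    {"EC0", "EC1", "ECS", "ECD", "PT2", "PT3", "PTS", "PTD", "VS2", "VS3", "VSS", "VSD", "NNC", "C5", "C6"}
)
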