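"""SMILES tokenization and string-fragment structural attributes.

A molecule's SMILES string is treated verbatim as a sequence of tokens (no
canonicalization, no valence model).  From the token stream two families of
structural attributes are extracted:

* local fragments — every single token (``Sk``), adjacent token pair
  (``SSk``) and adjacent token triple (``SSSk``), with pairs/triples
  normalized so that a fragment and its reversal map to one key;
* global codes — presence flags for bond symbols (``BOND``: ``=``, ``#``,
  stereo ``@``), heteroelements (``NOSP``: N/O/S/P) and halogens (``HALO``:
  F/Cl/Br/I), their pairwise (``PAIR``) and three-way (``HARD``)
  combinations, and the integer censuses ``CMAX`` (ring count), ``NMAX``,
  ``OMAX``, ``SMAX`` (nitrogen/oxygen/sulfur atom counts).

Each attribute is identified by an :class:`AttributeKey`; fragment codes are
rendered in fixed-width dot-padded slots (e.g. ``O...=...(...``) so reports
stay diffable.
"""

from __future__ import annotations

import re
from collections import Counter
from typing import NamedTuple


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be tokenized."""


class AttributeKey(NamedTuple):
    """One structural attribute: its family and a unique rendered code."""

    kind: str
    code: str


# token families
_TWO_LETTER = ("Cl", "Br", "Si")
_SINGLE = set("BCNOPSFIbcnops*=#()/\\.@-+0123456789")

_BRACKET_RE = re.compile(r"\[[^\[\]]+\]")
_BRACKET_ELEMENT_RE = re.compile(r"\[\d*([A-Za-z][a-z]?)")

SLOT_WIDTH = 4
N_SLOTS = 3


def tokenize_smiles(smiles: str) -> list[str]:
    """Split a SMILES string into atomic tokens.

    Two-letter element symbols (Cl, Br, Si), bracket-atom blocks
    (``[N+]``, ``[nH]`` ...) and ``%nn`` ring closures are kept whole;
    every other character is its own token.  The concatenation of the
    returned tokens reproduces the input exactly.
    """
    if not smiles:
        raise SmilesParseError("empty SMILES string")
    tokens: list[str] = []
    i, n = 0, len(smiles)
    while i < n:
        ch = smiles[i]
        if ch == "[":
            m = _BRACKET_RE.match(smiles, i)
            if m is None:
                raise SmilesParseError(f"unbalanced bracket at position {i} in {smiles!r}")
            tokens.append(m.group(0))
            i = m.end()
            continue
        if ch == "]":
            raise SmilesParseError(f"unmatched ']' at position {i} in {smiles!r}")
        if ch == "%":
            if i + 2 >= n or not smiles[i + 1 : i + 3].isdigit():
                raise SmilesParseError(f"malformed ring closure at position {i} in {smiles!r}")
            tokens.append(smiles[i : i + 3])
            i += 3
            continue
        if smiles[i : i + 2] in _TWO_LETTER:
            tokens.append(smiles[i : i + 2])
            i += 2
            continue
        if ch in _SINGLE:
            tokens.append(ch)
            i += 1
            continue
        raise SmilesParseError(f"unknown SMILES character {ch!r} at position {i} in {smiles!r}")
    depth = 0
    for t in tokens:
        if t == "(":
            depth += 1
        elif t == ")":
            depth -= 1
            if depth < 0:
                raise SmilesParseError(f"unbalanced ')' in {smiles!r}")
    if depth != 0:
        raise SmilesParseError(f"unbalanced '(' in {smiles!r}")
    return tokens


def _slot(token: str) -> str:
    """Render one token in a fixed-width dot-padded slot."""
    return token[:SLOT_WIDTH].ljust(SLOT_WIDTH, ".")


def render_fragment(tokens: tuple[str, ...]) -> str:
    """Fixed-width code for a 1–3 token fragment, e.g. ``('O','=','(')`` →
    ``O...=...(...``."""
    code = "".join(_slot(t) for t in tokens)
    return code.ljust(SLOT_WIDTH * N_SLOTS, ".")


def _normalize(frag: tuple[str, ...]) -> tuple[str, ...]:
    # a fragment and its reversal are the same attribute
    return min(frag, frag[::-1])


def extract_fragment_attributes(tokens: list[str]) -> Counter[AttributeKey]:
    """Sk/SSk/SSSk multiset for a token stream.

    Every token yields one Sk, every adjacent pair one SSk and every
    adjacent triple one SSSk; pair and triple keys are direction-normalized.
    """
    attrs: Counter[AttributeKey] = Counter()
    for t in tokens:
        attrs[AttributeKey("Sk", render_fragment((t,)))] += 1
    for a, b in zip(tokens, tokens[1:]):
        attrs[AttributeKey("SSk", render_fragment(_normalize((a, b))))] += 1
    for a, b, c in zip(tokens, tokens[1:], tokens[2:]):
        attrs[AttributeKey("SSSk", render_fragment(_normalize((a, b, c))))] += 1
    return attrs


def _bracket_element(token: str) -> str | None:
    m = _BRACKET_ELEMENT_RE.match(token)
    return m.group(1) if m else None


def _element_census(tokens: list[str]) -> Counter[str]:
    """Count heavy atoms per element symbol (case-folded to uppercase)."""
    census: Counter[str] = Counter()
    for t in tokens:
        if t.startswith("["):
            el = _bracket_element(t)
            if el is not None and el.upper() != "H":
                census[el.upper()] += 1
        elif t in _TWO_LETTER or (len(t) == 1 and t in "BCNOPSFIbcnops"):
            census[t.upper()] += 1
    return census


def ring_count(tokens: list[str]) -> int:
    """Number of rings = number of matched ring-closure label pairs."""
    open_labels: set[str] = set()
    rings = 0
    for t in tokens:
        if t.isdigit() or t.startswith("%"):
            label = t.lstrip("%")
            if label in open_labels:
                open_labels.remove(label)
                rings += 1
            else:
                open_labels.add(label)
    if open_labels:
        raise SmilesParseError(f"unmatched ring-closure label(s): {sorted(open_labels)}")
    return rings


def extract_global_attributes(tokens: list[str]) -> Counter[AttributeKey]:
    """Whole-molecule presence/census attributes.

    One BOND, NOSP, HALO and HARD key per molecule; one PAIR key per
    unordered pair of {BOND, NOSP, HALO}; one census key each for CMAX
    (ring count), NMAX, OMAX and SMAX.
    """
    census = _element_census(tokens)
    has_double = "=" in tokens
    has_triple = "#" in tokens
    has_stereo = any(t.startswith("[") and "@" in t for t in tokens) or "@" in tokens

    bond = "BOND" + ("=" if has_double else "-") + ("#" if has_triple else "-") + (
        "@" if has_stereo else "-"
    )
    nosp = "NOSP" + "".join(
        el if census.get(el, 0) else "-" for el in ("N", "O", "S", "P")
    )
    halo = "HALO" + "".join(
        (el if census.get(el, 0) else "-").ljust(2, ".") for el in ("F", "CL", "BR", "I")
    )

    attrs: Counter[AttributeKey] = Counter()
    attrs[AttributeKey("BOND", bond)] += 1
    attrs[AttributeKey("NOSP", nosp)] += 1
    attrs[AttributeKey("HALO", halo)] += 1
    for a, b in ((bond, nosp), (bond, halo), (nosp, halo)):
        attrs[AttributeKey("PAIR", f"PAIR({a},{b})")] += 1
    attrs[AttributeKey("HARD", f"HARD({bond},{nosp},{halo})")] += 1
    attrs[AttributeKey("CMAX", f"CMAX{ring_count(tokens)}")] += 1
    attrs[AttributeKey("NMAX", f"NMAX{census.get('N', 0)}")] += 1
    attrs[AttributeKey("OMAX", f"OMAX{census.get('O', 0)}")] += 1
    attrs[AttributeKey("SMAX", f"SMAX{census.get('S', 0)}")] += 1
    return attrs


def smiles_attributes(smiles: str) -> Counter[AttributeKey]:
    """All string-derived attributes of one SMILES."""
    tokens = tokenize_smiles(smiles)
    attrs = extract_fragment_attributes(tokens)
    attrs.update(extract_global_attributes(tokens))
    return attrs


SMILES_KINDS = frozenset(
    {"Sk", "SSk", "SSSk", "BOND", "NOSP", "HALO", "PAIR", "HARD", "CMAX", "NMAX", "OMAX", "SMAX"}
)
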