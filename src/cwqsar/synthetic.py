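"""Synthetic chalcone-derivative libraries with a planted SAR.

Generates decorated chalcones — the 1,3-diaryl-prop-2-en-1-one core
``O=C(C=C Ar_B) Ar_A`` with ring substituents drawn from a small grammar —
and assigns each compound an activity

    pIC50 = base + Σ effect(fragment) + Normal(0, noise_sd)

clipped to a chalcone-realistic range.  Because the true activity is an
exactly linear function of known fragment occurrences, every stage of the
pipeline (featurization, optimization, validation, interpretation) can be
checked against ground truth without any external data.

Defaults mirror the geometry of the modelled study: 190 compounds, pIC50
centred near 5.3 and clipped to [3.5, 7.0], with a strongly deactivating
dimethylamino substituent (−1.2 log units) among the planted effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# substituent grammar: name -> SMILES fragment inserted on an aryl ring
SUBSTITUENTS = {
    "H": "",
    "OCH3": "OC",
    "OH": "O",
    "F": "F",
    "Cl": "Cl",
    "Br": "Br",
    "NO2": "[N+](=O)[O-]",
    "NMe2": "N(C)C",
    "CH3": "C",
}

# B-ring replacements for the second phenyl
HETEROARYL = {
    "phenyl": None,  # substituted like the A ring
    "thiophen-2-yl": "c1cccs1",
    "furan-2-yl": "c1ccco1",
    "thiazol-2-yl": "c1nccs1",
    "pyridin-4-yl": "c1ccncc1",
}

DEFAULT_EFFECTS = {
    "OCH3": 0.4,
    "OH": 0.3,
    "F": 0.25,
    "Cl": 0.2,
    "NO2": -0.5,
    "NMe2": -1.2,
    "thiazol-2-yl": -0.6,
}


@dataclass
class GeneratorSpec:
    """Conditions of a synthetic library.

    effects maps fragment names (substituents or heteroaryl B-rings) to
    additive pIC50 contributions; fragments absent from the map are inert.
    """

    n_compounds: int = 190
    effects: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    base: float = 5.3
    noise_sd: float = 0.15
    pic50_range: tuple[float, float] = (3.5, 7.0)
    seed: int = 0
    substituents: dict[str, str] = field(default_factory=lambda: dict(SUBSTITUENTS))
    b_rings: dict[str, str | None] = field(default_factory=lambda: dict(HETEROARYL))

    def __post_init__(self):
        if self.n_compounds < 8:
            raise ValueError("need at least 8 compounds")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _aryl(para: str, meta: str) -> str:
    if not para and not meta:
        return "c1ccccc1"
    if para and not meta:
        return f"c1ccc({para})cc1"
    if meta and not para:
        return f"c1cccc({meta})c1"
    return f"c1cc({meta})c({para})cc1"


def generate_library(spec: GeneratorSpec) -> pd.DataFrame:
    """Draw a library of unique decorated chalcones with planted activities.

    Returns columns ``id``, ``smiles``, ``pic50`` and ``fragments`` (the
    '+'-joined non-H fragment names, for ground-truth checks).
    """
    rng = np.random.default_rng(spec.seed)
    sub_names = list(spec.substituents)
    b_names = list(spec.b_rings)
    seen: set[str] = set()
    rows = []
    attempts = 0
    max_attempts = 200 * spec.n_compounds
    while len(rows) < spec.n_compounds:
        attempts += 1
        if attempts > max_attempts:
            raise ValueError(
                "substituent grammar too small to yield "
                f"{spec.n_compounds} unique structures"
            )
        a_para, a_meta = rng.choice(sub_names, size=2)
        b_kind = b_names[rng.integers(len(b_names))]
        fragments = [n for n in (a_para, a_meta) if n != "H"]
        if spec.b_rings[b_kind] is None:
            b_para = str(rng.choice(sub_names))
            if b_para != "H":
                fragments.append(b_para)
            b_ring = _aryl(spec.substituents[b_para], "")
        else:
            fragments.append(b_kind)
            b_ring = spec.b_rings[b_kind]
        a_ring = _aryl(spec.substituents[a_para], spec.substituents[a_meta])
        smiles = f"O=C(C=C{b_ring}){a_ring}"
        if smiles in seen:
            continue
        seen.add(smiles)
        pic50 = spec.base + sum(spec.effects.get(f, 0.0) for f in fragments)
        if spec.noise_sd > 0:
            pic50 += rng.normal(0.0, spec.noise_sd)
        pic50 = float(np.clip(pic50, *spec.pic50_range))
        rows.append(
            {
                "id": f"syn{len(rows) + 1:03d}",
                "smiles": smiles,
                "pic50": round(pic50, 4),
                "fragments": "+".join(sorted(fragments)),
            }
        )
    return pd.DataFrame(rows)


def ground_truth(spec: GeneratorSpec) -> pd.DataFrame:
    """Expected promoter class per planted fragment (zero effects omitted)."""
    rows = [
        {
            "fragment": name,
            "effect": eff,
            "expected_class": "increase" if eff > 0 else "decrease",
        }
        for name, eff in spec.effects.items()
        if eff != 0
    ]
    return pd.DataFrame(rows)


def fragment_markers(library: pd.DataFrame) -> dict[str, set]:
    """Attribute keys that perfectly indicate each planted fragment.

    A marker of fragment *f* is an attribute present in every library
    compound bearing *f* and in no compound without it.  Because markers
    are exactly colinear with the fragment indicator, the sum of their
    learned correlation weights is the model's estimate of the fragment's
    activity contribution — which is how planted-sign recovery is judged.
    """
    from .features import featurize

    keysets = [set(featurize(s)) for s in library["smiles"]]
    frag_sets = [set(f.split("+")) if f else set() for f in library["fragments"]]
    all_fragments = set().union(*frag_sets)
    markers: dict[str, set] = {}
    for frag in sorted(all_fragments):
        with_f = [ks for ks, fs in zip(keysets, frag_sets) if frag in fs]
        without_f = [ks for ks, fs in zip(keysets, frag_sets) if frag not in fs]
        if not with_f or not without_f:
            continue
        markers[frag] = set.intersection(*with_f) - set().union(*without_f)
    return markers


def fragment_effect_estimates(predict, spec: GeneratorSpec) -> pd.DataFrame:
    """Model-estimated activity contribution of each planted fragment.

    ``predict`` maps a list of SMILES to predicted pIC50 (e.g. a fitted
    results object's ``predict``).  The estimate is the prediction
    difference between the parent chalcone decorated with the fragment and
    the bare parent — the direct structure-activity reading of the model.
    Returns columns fragment, effect, estimate, sign_recovered.
    """
    parent = "O=C(C=Cc1ccccc1)c1ccccc1"
    base = float(predict([parent])[0])
    rows = []
    for frag, eff in spec.effects.items():
        if eff == 0:
            continue
        if frag in spec.substituents:
            decorated = f"O=C(C=Cc1ccccc1){_aryl(spec.substituents[frag], '')}"
        elif frag in spec.b_rings and spec.b_rings[frag] is not None:
            decorated = f"O=C(C=C{spec.b_rings[frag]})c1ccccc1"
        else:
            raise KeyError(f"planted fragment {frag!r} is not in the grammar")
        est = float(predict([decorated])[0]) - base
        rows.append(
            {
                "fragment": frag,
                "effect": eff,
                "estimate": est,
                "sign_recovered": (est > 0) == (eff > 0),
            }
        )
    return pd.DataFrame(rows)
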