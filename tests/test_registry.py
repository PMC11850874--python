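"""Attribute registry: threshold rule, activity blocking, DCW arithmetic."""

from collections import Counter

import numpy as np
import pytest

from cwqsar.features import Compound
from cwqsar.registry import AttributeRegistry
from cwqsar.smiles import AttributeKey


def _toy_compounds():
    comps = [
        Compound("a", "CCO", 5.0),
        Compound("b", "CCN", 5.5),
        Compound("c", "CCO", 6.0),  # same attributes as a
        Compound("d", "CCCl", 4.5),
        Compound("e", "CCBr", 4.8),
        Compound("f", "CCI", 4.9),
    ]
    for c in comps:
        c.featurize()
    return comps


SPLITS = {"a": "TRN", "b": "TRN", "c": "iTRN", "d": "CAL", "e": "VAL", "f": "iTRN"}


def test_threshold_one_activates_training_attributes():
    comps = _toy_compounds()
    reg = AttributeRegistry.build(comps, SPLITS, threshold=1)
    for comp in comps:
        in_training = SPLITS[comp.id] in ("TRN", "iTRN")
        for key in comp.attributes:
            if in_training:
                assert reg.records[key].active


def test_validation_only_attribute_stays_blocked():
    comps = _toy_compounds()
    reg = AttributeRegistry.build(comps, SPLITS, threshold=1)
    br = next(k for k in comps[4].attributes if "Br" in k.code and k.kind == "Sk")
    assert not reg.records[br].active
    assert reg.records[br].correlation_weight == 0.0


def test_registry_determinism():
    r1 = AttributeRegistry.build(_toy_compounds(), SPLITS, threshold=1)
    r2 = AttributeRegistry.build(_toy_compounds(), SPLITS, threshold=1)
    assert {k: v.active for k, v in r1.records.items()} == {
        k: v.active for k, v in r2.records.items()
    }
    assert r1.to_frame().equals(r2.to_frame())


def test_higher_threshold_blocks_rare_attributes():
    comps = _toy_compounds()
    reg = AttributeRegistry.build(comps, SPLITS, threshold=2)
    # CCO attributes occur in compounds a (TRN) and c (iTRN): still active
    o_key = next(k for k in comps[0].attributes if k.kind == "Sk" and k.code.startswith("O"))
    assert reg.records[o_key].active
    # CCI attributes occur once in training
    i_key = next(k for k in comps[5].attributes if k.kind == "Sk" and k.code.startswith("I"))
    assert not reg.records[i_key].active


def test_blocked_weight_cannot_be_set():
    comps = _toy_compounds()
    reg = AttributeRegistry.build(comps, SPLITS, threshold=1)
    br = next(k for k in comps[4].attributes if "Br" in k.code and k.kind == "Sk")
    with pytest.raises(ValueError):
        reg.set_weights({br: 1.0})


def test_empty_training_rejected():
    comps = _toy_compounds()
    splits = {i: "VAL" for i in "abcdef"}
    with pytest.raises(ValueError):
        AttributeRegistry.build(comps, splits, threshold=1)


# ---- DCW -------------------------------------------------------------------
def test_dcw_zero_weights():
    comps = _toy_compounds()
    reg = AttributeRegistry.build(comps, SPLITS, threshold=1)
    assert reg.compute_dcw(comps[0]).dcw == 0.0


def test_dcw_hand_oracle():
    """Three hand-weighted attributes on a toy SMILES sum exactly."""
    comps = _toy_compounds()
    reg = AttributeRegistry.build(comps, SPLITS, threshold=1)
    comp = comps[0]  # CCO
    c_sk = AttributeKey("Sk", "C...........")
    o_sk = AttributeKey("Sk", "O...........")
    cc = AttributeKey("SSk", "C...C.......")
    reg.set_weights({c_sk: 0.5, o_sk: -1.0, cc: 0.25})
    # CCO has C twice, O once, CC pair once
    expected = 2 * 0.5 + 1 * (-1.0) + 1 * 0.25
    assert reg.compute_dcw(comp).dcw == pytest.approx(expected)


def test_dcw_multiplicity_and_linearity():
    comps = _toy_compounds()
    reg = AttributeRegistry.build(comps, SPLITS, threshold=1)
    c_sk = AttributeKey("Sk", "C...........")
    reg.set_weights({c_sk: 0.7})
    base = reg.compute_dcw(comps[0]).dcw
    assert base == pytest.approx(2 * 0.7)  # C occurs twice in CCO
    reg.set_weights({c_sk: 1.4})
    assert reg.compute_dcw(comps[0]).dcw == pytest.approx(2 * base)


def test_dcw_hybrid_additivity(small_model):
    reg = small_model.registry
    rng = np.random.default_rng(0)
    reg.set_weights({k: rng.normal() for k in reg.active_keys})
    for comp in small_model.compounds[:10]:
        value = reg.compute_dcw(comp)
        assert value.dcw == pytest.approx(value.smiles_part + value.graph_part, abs=1e-12)


def test_unknown_attribute_contributes_zero():
    comps = _toy_compounds()
    reg = AttributeRegistry.build(comps, SPLITS, threshold=1)
    rng = np.random.default_rng(1)
    reg.set_weights({k: rng.normal() for k in reg.active_keys})
    novel = Compound("x", "c1ccncc1")  # pyridine: attributes unseen above
    before = reg.compute_dcw(comps[0]).dcw
    _ = reg.compute_dcw(novel)
    assert reg.compute_dcw(comps[0]).dcw == before


def test_count_matrix_matches_compute_dcw(small_model):
    reg = small_model.registry
    rng = np.random.default_rng(2)
    w = {k: rng.normal() for k in reg.active_keys}
    reg.set_weights(w)
    X, keys = reg.count_matrix(small_model.compounds)
    wv = np.array([w[k] for k in keys])
    dcw_matrix = X @ wv
    for i, comp in enumerate(small_model.compounds[:15]):
        assert dcw_matrix[i] == pytest.approx(reg.compute_dcw(comp).dcw)
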