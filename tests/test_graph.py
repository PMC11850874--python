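"""Hydrogen-suppressed graph construction and topological invariants.

Path counts and valence shells are checked against exhaustive DFS/BFS
oracles on random graphs; attribute extraction must not depend on which
atom a SMILES is written from.
"""

import itertools

import networkx as nx
import numpy as np
import pytest

from cwqsar.graph import (
    RingCode,
    build_hsg,
    graph_attributes,
    morgan_connectivity,
    nearest_neighbor_codes,
    path_counts,
    ring_codes,
    valence_shells,
)
from cwqsar.smiles import SmilesParseError


# ---- oracles ---------------------------------------------------------------
def brute_force_paths(g, v, length):
    """Count simple paths of exactly `length` edges from v by enumeration."""
    total = 0
    for nodes in itertools.permutations([u for u in g.nodes if u != v], length):
        walk = (v, *nodes)
        if all(g.has_edge(a, b) for a, b in zip(walk, walk[1:])):
            total += 1
    return total


def brute_force_shell(g, v, order):
    dist = nx.single_source_shortest_path_length(g, v)
    return sum(g.degree(u) for u, d in dist.items() if d == order)


# ---- construction ----------------------------------------------------------
def test_benzene_graph():
    g = build_hsg("c1ccccc1")
    assert g.number_of_nodes() == 6
    assert g.number_of_edges() == 6
    assert all(g.nodes[v]["aromatic"] for v in g.nodes)


def test_chalcone_graph(chalcone):
    g = build_hsg(chalcone)
    assert g.number_of_nodes() == 16  # C15H12O: 16 heavy atoms
    assert g.number_of_edges() == 17  # 16 - 1 + 2 rings


def test_single_atom():
    g = build_hsg("C")
    assert g.number_of_nodes() == 1 and g.number_of_edges() == 0
    assert path_counts(g, 2)[0] == 0 and path_counts(g, 3)[0] == 0
    assert nearest_neighbor_codes(g)[0] == "000"


def test_bracket_hydrogen_dropped():
    g = build_hsg("c1cc[nH]c1")
    assert g.number_of_nodes() == 5
    elements = {g.nodes[v]["element"] for v in g.nodes}
    assert elements == {"C", "N"}


@pytest.mark.parametrize("bad", ["C1CC", "CC=", "1CC"])
def test_build_errors(bad):
    with pytest.raises(SmilesParseError):
        build_hsg(bad)


# ---- invariants ------------------------------------------------------------
def test_benzene_invariants():
    g = build_hsg("c1ccccc1")
    ec = morgan_connectivity(g)
    assert all(ec[v] == (2, 4) for v in g.nodes)
    assert all(c == 2 for c in path_counts(g, 2).values())
    assert all(c == 2 for c in path_counts(g, 3).values())
    assert all(s == 4 for s in valence_shells(g, 2).values())


def test_path_graph_invariants():
    g = build_hsg("CCC")  # A-B-C
    ec = morgan_connectivity(g)
    assert ec[1] == (2, 2)
    assert valence_shells(g, 2)[0] == 1  # degree of C at distance 2


def test_star_graph_paths():
    g = build_hsg("C(C)(C)C")  # K1,3, center is vertex 0
    assert path_counts(g, 2)[0] == 0
    assert path_counts(g, 2)[1] == 2


def test_carbonyl_carbon(chalcone):
    g = build_hsg(chalcone)
    assert morgan_connectivity(g)[1][0] == 3
    assert nearest_neighbor_codes(g)[1] == "321"


def test_dimethylamino_nitrogen():
    g = build_hsg("CN(C)C")
    assert nearest_neighbor_codes(g)[1] == "330"


def test_random_graphs_match_oracles():
    rng = np.random.default_rng(42)
    for _ in range(200):
        n = int(rng.integers(2, 9))
        g = nx.gnp_random_graph(n, float(rng.uniform(0.2, 0.8)), seed=int(rng.integers(1 << 30)))
        pt2 = path_counts(g, 2)
        pt3 = path_counts(g, 3)
        s2 = valence_shells(g, 2)
        s3 = valence_shells(g, 3)
        for v in g.nodes:
            assert pt2[v] == brute_force_paths(g, v, 2)
            assert pt3[v] == brute_force_paths(g, v, 3)
            assert s2[v] == brute_force_shell(g, v, 2)
            assert s3[v] == brute_force_shell(g, v, 3)


def test_degree_sum_identity(default_library):
    _, lib = default_library
    for smiles in lib["smiles"].head(20):
        g = build_hsg(smiles)
        ec0_sum = sum(e0 for e0, _ in morgan_connectivity(g).values())
        assert ec0_sum == 2 * g.number_of_edges()


# ---- ring codes ------------------------------------------------------------
def test_ring_codes_benzene():
    codes = ring_codes(build_hsg("c1ccccc1"))
    assert codes == {RingCode(6, True, 0): 1}


def test_ring_codes_thiazole():
    codes = ring_codes(build_hsg("c1nccs1"))
    assert codes == {RingCode(5, True, 2): 1}


def test_ring_codes_size_filter():
    assert not ring_codes(build_hsg("C1CCCCCCC1"))  # cyclooctane ignored


def test_ring_codes_saturated():
    assert ring_codes(build_hsg("C1CCCCC1")) == {RingCode(6, False, 0): 1}


# ---- full attribute extraction ---------------------------------------------
def test_graph_attribute_codes():
    attrs = graph_attributes(build_hsg("c1ccccc1"))
    codes = {k.code for k in attrs}
    assert "EC0-C...2..." in codes
    assert "EC1-C...4..." in codes
    assert "ECD-C...2..." in codes  # |2 - 4|
    assert "C6...AH.0..." in codes


def test_attribute_permutation_invariance():
    # same molecule written from three different start atoms
    variants = ["Cc1ccccc1", "c1ccccc1C", "c1ccc(C)cc1"]
    references = [graph_attributes(build_hsg(s)) for s in variants]
    assert references[0] == references[1] == references[2]


def test_ether_pt3_oxygen_reachable():
    # an aryl-ether oxygen with pt3 = 3 must be emitted for suitable molecules
    attrs = graph_attributes(build_hsg("CCCOc1ccccc1"))
    assert any(k.code.startswith("PT3-O...3") for k in attrs)


def test_rdkit_cross_check(default_library):
    """Independent parse: heavy-atom and ring counts agree with RDKit."""
    rdkit = pytest.importorskip("rdkit")
    from rdkit import Chem

    _, lib = default_library
    for smiles in lib["smiles"].head(25):
        mol = Chem.MolFromSmiles(smiles)
        assert mol is not None, smiles
        g = build_hsg(smiles)
        assert g.number_of_nodes() == mol.GetNumHeavyAtoms()
        assert g.number_of_edges() == mol.GetNumBonds()
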