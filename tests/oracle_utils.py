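"""Independent brute-force subgraph-isomorphism oracle (networkx VF2).

Substructure matching is subgraph *monomorphism* (extra target bonds
between mapped atoms are allowed). Atom compatibility mirrors the
verifier's semantics: element symbols must agree; a query atom with zero
formal charge / unset isotope is a wildcard for those properties, a
non-zero one must match exactly. Bond types (1/2/3/aromatic) must agree.
"""

from __future__ import annotations

import random

import networkx as nx
from rdkit import Chem, rdBase

from chemreg.chem import Molecule


def to_graph(mol: Molecule) -> nx.Graph:
    g = nx.Graph()
    for idx, (symbol, charge, isotope, _h) in enumerate(mol.atoms):
        g.add_node(idx, symbol=symbol, charge=charge, isotope=isotope)
    for i, j, order in mol.bonds:
        g.add_edge(i, j, order=order)
    return g


def _node_match(target_attrs, query_attrs):
    if target_attrs["symbol"] != query_attrs["symbol"]:
        return False
    if query_attrs["charge"] != 0 and \
            query_attrs["charge"] != target_attrs["charge"]:
        return False
    if query_attrs["isotope"] != 0 and \
            query_attrs["isotope"] != target_attrs["isotope"]:
        return False
    return True


def _edge_match(target_attrs, query_attrs):
    return target_attrs["order"] == query_attrs["order"]


def brute_force_substructure(target: Molecule, query: Molecule) -> bool:
    gm = nx.algorithms.isomorphism.GraphMatcher(
        to_graph(target), to_graph(query),
        node_match=_node_match, edge_match=_edge_match)
    return gm.subgraph_is_monomorphic()


def edge_deleted_query(target: Molecule, rng: random.Random
                       ) -> Molecule | None:
    """A query built by deleting one random bond of the target and keeping
    one connected component; None when the result does not survive
    re-perception (e.g. a broken aromatic ring)."""
    rd = target.rdmol
    if rd.GetNumBonds() == 0:
        return None
    bond = rd.GetBondWithIdx(rng.randrange(rd.GetNumBonds()))
    em = Chem.RWMol(rd)
    em.RemoveBond(bond.GetBeginAtomIdx(), bond.GetEndAtomIdx())
    frags = Chem.GetMolFrags(em.GetMol(), asMols=True, sanitizeFrags=False)
    frag = frags[rng.randrange(len(frags))]
    try:
        with rdBase.BlockLogs():
            Chem.SanitizeMol(frag)
    except Exception:
        return None
    return Molecule(frag, source_text=Chem.MolToSmiles(frag))
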