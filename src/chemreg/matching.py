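"""Structure matching and similarity.

The screening fingerprint hashes the labels of all simple linear atom paths
of 1..L atoms (default L=7) into a fixed-width bit vector. Path labels use
element symbols and bond types (single/double/triple/aromatic) only —
deliberately *coarser* than the verifier's atom compatibility (which lets a
neutral query atom match a charged target atom), so the screen has the
subset property: whenever the verifier embeds query Q in target T,
``fp(Q) & fp(T) == fp(Q)``. The screen is thus a sound necessary condition
with no false negatives; verification is exact subgraph matching.

Similarity on fingerprints, with a = |A|, b = |B|, c = |A ∩ B|:

* Tanimoto (Jaccard):  c / (a + b − c)
* Tversky:             c / (α(a − c) + β(b − c) + c)
* substructure-Euclidean: c / a  — the fraction of the first (query)
  fingerprint's bits present in the second.

Two empty fingerprints are identical, so 0/0 is defined as 1.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

from rdkit import Chem

from .chem import (Molecule, element_counts, parse_formula, parse_structure,
                   structure_key)
from .errors import ParamsMismatchError

__all__ = [
    "FingerprintParams", "Fingerprint", "MatchResult", "fingerprint",
    "match_substructure", "match_exact", "match_smarts", "match_formula",
    "similarity",
]


@dataclass(frozen=True)
class FingerprintParams:
    """Generation parameters; fingerprints are comparable only when these
    match (tracked through ``params_id``)."""

    n_bits: int = 2048
    max_path_atoms: int = 7

    @property
    def params_id(self) -> str:
        return f"linpath-{self.max_path_atoms}/{self.n_bits}/v1"


DEFAULT_PARAMS = FingerprintParams()


@dataclass(frozen=True)
class Fingerprint:
    bits: int            # bit vector packed into a Python int
    n_bits: int
    popcount: int
    params_id: str

    def to_bytes(self) -> bytes:
        return self.bits.to_bytes((self.n_bits + 7) // 8, "little")

    @classmethod
    def from_bytes(cls, raw: bytes, n_bits: int, params_id: str
                   ) -> "Fingerprint":
        bits = int.from_bytes(raw, "little")
        return cls(bits=bits, n_bits=n_bits, popcount=bits.bit_count(),
                   params_id=params_id)

    def is_subset_of(self, other: "Fingerprint") -> bool:
        if self.params_id != other.params_id:
            raise ParamsMismatchError(
                f"{self.params_id} vs {other.params_id}")
        return self.bits & other.bits == self.bits


@dataclass(frozen=True)
class MatchResult:
    matched: bool
    atom_map: frozenset[int]   # target atom indices of one embedding


def _atom_label(atom: Chem.Atom) -> str:
    # element only: the verifier treats neutral query atoms as wildcards
    # for charge/isotope, so finer labels would break screening soundness
    return atom.GetSymbol()


_BOND_LABEL = {
    Chem.BondType.SINGLE: "1",
    Chem.BondType.DOUBLE: "2",
    Chem.BondType.TRIPLE: "3",
    Chem.BondType.AROMATIC: "a",
}


def _bond_label(bond: Chem.Bond) -> str:
    if bond.GetIsAromatic():
        return "a"
    return _BOND_LABEL.get(bond.GetBondType(), "1")


def _path_labels(mol: Chem.Mol, max_atoms: int) -> set[str]:
    """Canonical labels of all simple linear paths of 1..max_atoms atoms."""
    n = mol.GetNumAtoms()
    atom_labels = [_atom_label(a) for a in mol.GetAtoms()]
    nbrs: list[list[tuple[int, str]]] = [[] for _ in range(n)]
    for b in mol.GetBonds():
        i, j = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        lab = _bond_label(b)
        nbrs[i].append((j, lab))
        nbrs[j].append((i, lab))
    labels: set[str] = set()

    def dfs(last: int, visited: list[int], parts: list[str]) -> None:
        forward = ".".join(parts)
        labels.add(min(forward, ".".join(reversed(parts))))
        if len(visited) >= max_atoms:
            return
        for nxt, blab in nbrs[last]:
            if nxt in visited:
                continue
            visited.append(nxt)
            parts.append(blab)
            parts.append(atom_labels[nxt])
            dfs(nxt, visited, parts)
            parts.pop()
            parts.pop()
            visited.pop()

    for start in range(n):
        dfs(start, [start], [atom_labels[start]])
    return labels


def fingerprint(mol: Molecule, params: FingerprintParams = DEFAULT_PARAMS
                ) -> Fingerprint:
    """Hashed linear-path fingerprint of a (possibly multi-component)
    molecule. Paths never cross components, so the fingerprint of a mixture
    equals the bitwise OR of its component fingerprints."""
    bits = 0
    for label in _path_labels(mol.rdmol, params.max_path_atoms):
        digest = hashlib.sha1(label.encode()).digest()
        idx = int.from_bytes(digest[:8], "big") % params.n_bits
        bits |= 1 << idx
    return Fingerprint(bits=bits, n_bits=params.n_bits,
                       popcount=bits.bit_count(),
                       params_id=params.params_id)


def match_substructure(target: Molecule, query: Molecule) -> MatchResult:
    """Subgraph-match ``query`` (a molecule parsed as a pattern) in
    ``target``. Element, aromaticity, charge and bond order are respected;
    implicit hydrogens on the query do not constrain the target. Returns
    one embedding's target-atom set."""
    if query.rdmol.GetNumAtoms() == 0:
        return MatchResult(False, frozenset())
    hit = target.rdmol.GetSubstructMatch(query.rdmol)
    if not hit:
        return MatchResult(False, frozenset())
    return MatchResult(True, frozenset(hit))


def match_exact(target: Molecule, query: Molecule) -> bool:
    """Full-structure match: identical structure keys."""
    return structure_key(target).key == structure_key(query).key


def match_smarts(target: Molecule, smarts: str | Molecule) -> bool:
    """SMARTS pattern match using the toolkit's SMARTS dialect."""
    if isinstance(smarts, Molecule):
        pattern = smarts
    else:
        pattern = parse_structure(smarts, format="smarts")
    return target.rdmol.HasSubstructMatch(pattern.rdmol)


def match_formula(mol: Molecule, formula: str) -> bool:
    """True iff the molecule's element-count multiset equals the formula's
    (element order in the input is irrelevant; charge ignored)."""
    return element_counts(mol) == parse_formula(formula)


def similarity(a: Fingerprint, b: Fingerprint, metric: str = "tanimoto",
               alpha: float = 1.0, beta: float = 1.0) -> float:
    """Fingerprint similarity in [0, 1].

    ``tversky`` and ``euclid_sub`` are asymmetric: the first argument is
    the query fingerprint.
    """
    if a.params_id != b.params_id:
        raise ParamsMismatchError(f"{a.params_id} vs {b.params_id}")
    ca, cb = a.popcount, b.popcount
    c = (a.bits & b.bits).bit_count()
    if metric == "tanimoto":
        denom = ca + cb - c
        return 1.0 if denom == 0 else c / denom
    if metric == "tversky":
        if alpha < 0 or beta < 0:
            raise ValueError("tversky weights must be non-negative")
        denom = alpha * (ca - c) + beta * (cb - c) + c
        return 1.0 if denom == 0 else c / denom
    if metric == "euclid_sub":
        return 1.0 if ca == 0 else c / ca
    raise ValueError(f"unknown similarity metric {metric!r}")
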