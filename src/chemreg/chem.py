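"""Core chemistry: parsing, canonicalization, structure keys, mass, formula.

A :class:`Molecule` wraps an RDKit ``Mol`` together with the original input
text. All chemistry (aromaticity perception, canonical SMILES, InChIKey)
is delegated to RDKit so that storage and matching share one consistent
aromaticity model.

Structure identity throughout the registry is the standard InChIKey; for
species the InChI algorithm cannot represent, a deterministic fallback key
``"XK-" + md5(canonical SMILES)`` keeps the unique-constraint mechanism
intact.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field

from rdkit import Chem, rdBase
from rdkit.Chem import Descriptors

from .errors import (KeyGenerationError, ParseError, UnknownElementError,
                     ValenceError)

__all__ = [
    "Molecule", "StructureKey", "parse_structure", "split_components",
    "structure_key", "molecular_weight", "gross_formula", "canonical_form",
    "element_counts", "parse_formula",
]

# V2000 counts line: two 3-char ints followed (eventually) by the version tag
_V2000_RE = re.compile(r"^\s*\d{1,3}\s+\d{1,3}.*V2000\s*$", re.MULTILINE)

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class StructureKey:
    """Unique key of a stored structure.

    Either a 27-character standard InChIKey (``XXXXXXXXXXXXXX-YYYYYYYYYY-Z``)
    or the fallback ``"XK-" + 32-hex-digest`` of the canonical SMILES.
    """

    key: str

    @property
    def is_fallback(self) -> bool:
        return self.key.startswith("XK-")

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.key


@dataclass
class Molecule:
    """A parsed chemical graph.

    ``atoms`` and ``bonds`` expose the graph in toolkit-independent form
    (used by the fingerprinter and by test oracles); ``rdmol`` is the
    underlying RDKit molecule.
    """

    rdmol: Chem.Mol
    source_text: str = ""
    _components: list["Molecule"] | None = field(default=None, repr=False)

    @property
    def atoms(self) -> list[tuple[str, int, int, int]]:
        """(element symbol, formal charge, isotope, implicit+explicit H)."""
        return [
            (a.GetSymbol(), a.GetFormalCharge(), a.GetIsotope(),
             a.GetTotalNumHs())
            for a in self.rdmol.GetAtoms()
        ]

    @property
    def bonds(self) -> list[tuple[int, int, object]]:
        """(begin index, end index, order) with order in {1, 2, 3, 'ar'}."""
        out = []
        for b in self.rdmol.GetBonds():
            out.append((b.GetBeginAtomIdx(), b.GetEndAtomIdx(),
                        _bond_order(b)))
        return out

    @property
    def num_heavy_atoms(self) -> int:
        return self.rdmol.GetNumAtoms()

    @property
    def num_components(self) -> int:
        return len(Chem.GetMolFrags(self.rdmol))


def _bond_order(bond: Chem.Bond):
    if bond.GetIsAromatic():
        return "ar"
    t = bond.GetBondType()
    if t == Chem.BondType.SINGLE:
        return 1
    if t == Chem.BondType.DOUBLE:
        return 2
    if t == Chem.BondType.TRIPLE:
        return 3
    return "ar" if t == Chem.BondType.AROMATIC else 1


def _looks_like_molfile(text: str) -> bool:
    return bool(_V2000_RE.search(text))


def parse_structure(text: str, format: str | None = None, *,
                    on_valence_error: str = "reject") -> Molecule:
    """Parse SMILES, SMARTS or a V2000 molfile block into a Molecule.

    ``format`` is one of ``smiles``, ``molfile``, ``smarts`` or ``None``
    for auto-detection (molfile iff a V2000 counts line is present).
    Whitespace inside SMILES is stripped before parsing — structures are
    sometimes printed with spaces around bond symbols.

    ``on_valence_error``: ``reject`` raises :class:`ValenceError` for
    chemically impossible atoms; ``accept`` keeps the molecule as drawn
    (only ring/aromaticity perception is run).
    """
    if not text or not text.strip():
        raise ParseError("empty structure text", reason="empty input")
    if format is None:
        format = "molfile" if _looks_like_molfile(text) else "smiles"
    if format not in ("smiles", "molfile", "smarts"):
        raise ParseError(f"unknown structure format {format!r}",
                         reason="bad format")

    with rdBase.BlockLogs():
        if format == "smarts":
            mol = Chem.MolFromSmarts(text)
            if mol is None:
                raise ParseError(f"invalid SMARTS: {text!r}",
                                 reason="SMARTS syntax")
            return Molecule(mol, source_text=text)

        if format == "molfile":
            mol = Chem.MolFromMolBlock(text, sanitize=False,
                                       removeHs=True)
            if mol is None:
                raise ParseError("invalid molfile block",
                                 reason="molfile syntax")
        else:
            cleaned = "".join(text.split())
            mol = Chem.MolFromSmiles(cleaned, sanitize=False)
            if mol is None:
                raise ParseError(f"invalid SMILES: {cleaned!r}",
                                 reason="SMILES syntax")
        try:
            Chem.SanitizeMol(mol)
        except Chem.AtomValenceException as exc:
            if on_valence_error == "accept":
                _partial_sanitize(mol)
            else:
                raise ValenceError(str(exc), reason="valence") from exc
        except (Chem.KekulizeException, Chem.AtomKekulizeException) as exc:
            raise ParseError(str(exc), reason="kekulization") from exc
        except Exception as exc:  # other sanitize failures
            raise ParseError(str(exc), reason="sanitization") from exc
    return Molecule(mol, source_text=text)


def _partial_sanitize(mol: Chem.Mol) -> None:
    """Sanitize skipping the valence check (accept-as-is policy)."""
    flags = (Chem.SanitizeFlags.SANITIZE_ALL
             ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES)
    Chem.SanitizeMol(mol, sanitizeOps=flags)


def split_components(mol: Molecule) -> list[Molecule]:
    """Split a molecule into connected components, input order preserved."""
    if mol._components is not None:
        return mol._components
    frags = Chem.GetMolFrags(mol.rdmol, asMols=True, sanitizeFrags=False)
    if len(frags) == 1:
        mol._components = [mol]
        return mol._components
    mol._components = [
        Molecule(f, source_text=Chem.MolToSmiles(f)) for f in frags
    ]
    return mol._components


def canonical_form(mol: Molecule) -> str:
    """Canonical SMILES, invariant under input atom ordering."""
    return Chem.MolToSmiles(mol.rdmol)


def structure_key(mol: Molecule) -> StructureKey:
    """Standard InChIKey of a single-component molecule.

    Falls back to ``"XK-" + md5(canonical SMILES)`` when the InChI
    algorithm cannot represent the species (e.g. certain radicals or
    polymer-like inputs).
    """
    if mol.num_components != 1:
        raise ValueError(
            "structure_key requires a single connected component; "
            "split_components() first")
    key = None
    with rdBase.BlockLogs():
        try:
            key = Chem.MolToInchiKey(mol.rdmol)
        except Exception:
            key = None
    if key:
        return StructureKey(key)
    try:
        digest = hashlib.md5(canonical_form(mol).encode()).hexdigest()
    except Exception as exc:  # pragma: no cover - canonical SMILES failed too
        raise KeyGenerationError(
            f"cannot derive a key for {mol.source_text!r}") from exc
    return StructureKey("XK-" + digest)


def molecular_weight(mol: Molecule) -> float:
    """Average molecular weight in g/mol, implicit hydrogens included."""
    for atom in mol.rdmol.GetAtoms():
        if atom.GetAtomicNum() == 0:
            raise UnknownElementError(
                f"atom {atom.GetIdx()} has no element assigned")
    return float(Descriptors.MolWt(mol.rdmol))


def element_counts(mol: Molecule) -> dict[str, int]:
    """Element -> count map including implicit/explicit hydrogens."""
    counts: dict[str, int] = {}
    for a in mol.rdmol.GetAtoms():
        counts[a.GetSymbol()] = counts.get(a.GetSymbol(), 0) + 1
        h = a.GetTotalNumHs()
        if h:
            counts["H"] = counts.get("H", 0) + h
    return counts


def _hill_order(counts: dict[str, int]) -> str:
    parts = []
    rest = dict(counts)
    if "C" in rest:
        parts.append(("C", rest.pop("C")))
        if "H" in rest:
            parts.append(("H", rest.pop("H")))
        parts.extend(sorted(rest.items()))
    else:
        parts.extend(sorted(rest.items()))
    return "".join(f"{el}{n if n > 1 else ''}" for el, n in parts)


def gross_formula(mol: Molecule) -> str:
    """Gross formula in Hill order (C, H, then alphabetical); the net
    charge is excluded — formula search compares element counts only."""
    if mol.num_components != 1:
        raise ValueError("gross_formula requires a single component")
    return _hill_order(element_counts(mol))


def parse_formula(text: str) -> dict[str, int]:
    """Parse a gross-formula string (any element order) into counts.

    Charge suffixes (``+``/``-`` with optional digits) are ignored, matching
    the charge-excluded convention of :func:`gross_formula`.
    """
    text = text.strip()
    body = re.sub(r"[+-]\d*$", "", text)
    if not body:
        raise ParseError(f"empty formula: {text!r}", reason="formula")
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(body):
        if m.start() != pos:
            raise ParseError(f"invalid formula {text!r}", position=pos,
                             reason="formula syntax")
        el, num = m.group(1), m.group(2)
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = m.end()
    if pos != len(body):
        raise ParseError(f"invalid formula {text!r}", position=pos,
                         reason="formula syntax")
    return counts
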