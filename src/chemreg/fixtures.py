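"""Deterministic synthetic molecule and SD-file fixture generator.

Molecules are assembled from a small fragment grammar — ring scaffolds
(carbocycles, N/O/S heterocycles) decorated with short substituents
(alkyl chains, hydroxy, amino, halogen, nitrile, carboxyl) attached at
atoms with free valence — so every generated structure is parseable and
valence-legal by construction. A configurable fraction of records are
mixtures of 2–3 components with percentages summing to ≤ 100.

Everything is driven by one ``random.Random(seed)``: the same
:class:`FixtureSpec` always produces byte-identical SD-file output and an
identical manifest of expected structure-key sets (the manifest is the
oracle used by round-trip and search tests).
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, asdict

from rdkit import Chem, rdBase

from .chem import Molecule, parse_structure, split_components, structure_key
from .sdf import write_sdf_record, PERCENTAGE_TAG

__all__ = ["FixtureSpec", "FixtureRecord", "gen_molecules", "gen_fixtures"]

_SCAFFOLDS = [
    "c1ccccc1", "c1ccncc1", "c1ccoc1", "c1ccsc1", "c1cc[nH]c1",
    "C1CCCCC1", "C1CCCC1", "C1CCOC1", "C1CCNC1", "C1CCOCC1", "C1CCNCC1",
    "CCCC", "CCCCC", "CCOCC", "CCNCC", "CC(C)C", "C1CC1", "c1cnccn1",
]

_SUBSTITUENTS = [
    "C", "CC", "CCC", "C(C)C", "O", "OC", "N", "NC", "F", "Cl", "Br",
    "C#N", "C(=O)O", "C(=O)C", "C=C", "S", "CO", "CN",
]


@dataclass(frozen=True)
class FixtureSpec:
    n_compounds: int = 100
    mixture_fraction: float = 0.2
    max_heavy_atoms: int = 18
    seed: int = 0
    name_prefix: str = "CR-"


@dataclass
class FixtureRecord:
    name: str
    smiles: list[str]                 # one canonical SMILES per component
    percentages: list[float | None]
    cas: str | None
    keys: list[str]                   # sorted distinct structure keys

    @property
    def combined_smiles(self) -> str:
        return ".".join(self.smiles)


def _attach(rng: random.Random, scaffold: Chem.Mol, sub_smiles: str
            ) -> Chem.Mol | None:
    """Bond the first atom of a substituent to a random scaffold atom with
    free valence; returns None when no attachment point exists."""
    sub = Chem.MolFromSmiles(sub_smiles)
    candidates = [a.GetIdx() for a in scaffold.GetAtoms()
                  if a.GetTotalNumHs() > 0]
    if not candidates:
        return None
    at = rng.choice(candidates)
    combined = Chem.RWMol(Chem.CombineMols(scaffold, sub))
    combined.AddBond(at, scaffold.GetNumAtoms(), Chem.BondType.SINGLE)
    mol = combined.GetMol()
    try:
        with rdBase.BlockLogs():
            Chem.SanitizeMol(mol)
    except Exception:
        return None
    return mol


def _random_component(rng: random.Random, max_heavy: int) -> str:
    for _ in range(20):
        mol = Chem.MolFromSmiles(rng.choice(_SCAFFOLDS))
        n_subs = rng.randint(0, 3)
        ok = True
        for _ in range(n_subs):
            if mol.GetNumAtoms() >= max_heavy:
                break
            sub = rng.choice(_SUBSTITUENTS)
            grown = _attach(rng, mol, sub)
            if grown is None:
                ok = False
                break
            if grown.GetNumAtoms() > max_heavy:
                continue
            mol = grown
        if ok and mol.GetNumAtoms() <= max_heavy:
            return Chem.MolToSmiles(mol)
    return "CCO"  # unreachable in practice; keeps the generator total


def _cas_like(rng: random.Random) -> str:
    return f"{rng.randint(50, 999999)}-{rng.randint(10, 99)}-" \
           f"{rng.randint(0, 9)}"


def gen_molecules(spec: FixtureSpec) -> list[FixtureRecord]:
    """Generate the deterministic fixture set for ``spec``. Exactly
    ``round(n_compounds * mixture_fraction)`` records are mixtures."""
    rng = random.Random(spec.seed)
    n_mix = round(spec.n_compounds * spec.mixture_fraction)
    mixture_idx = set(rng.sample(range(spec.n_compounds), n_mix)) \
        if n_mix else set()
    records: list[FixtureRecord] = []
    cas_pool: list[str] = []
    for i in range(spec.n_compounds):
        if i in mixture_idx:
            k = rng.randint(2, 3)
            smiles = [_random_component(rng, spec.max_heavy_atoms)
                      for _ in range(k)]
            if rng.random() < 0.5:
                shares = [rng.uniform(5, 90 / k) for _ in range(k)]
                percentages = [round(s, 1) for s in shares]
            else:
                percentages = [None] * k
        else:
            smiles = [_random_component(rng, spec.max_heavy_atoms)]
            percentages = [None]
        if rng.random() < 0.1:
            cas = None
        elif cas_pool and rng.random() < 0.05:
            cas = rng.choice(cas_pool)      # CAS is not unique
        else:
            cas = _cas_like(rng)
            cas_pool.append(cas)
        keys = sorted({structure_key(parse_structure(s)).key
                       for s in smiles})
        records.append(FixtureRecord(
            name=f"{spec.name_prefix}{i:06d}", smiles=smiles,
            percentages=percentages, cas=cas, keys=keys))
    return records


def gen_fixtures(spec: FixtureSpec, out_path: str) -> list[FixtureRecord]:
    """Write ``<out_path>`` as an SD-file plus ``<out_path>.manifest.json``
    listing each record's expected structure-key set."""
    records = gen_molecules(spec)
    with open(out_path, "w", newline="\n") as fh:
        for rec in records:
            mols = [parse_structure(s).rdmol for s in rec.smiles]
            combined = mols[0]
            for m in mols[1:]:
                combined = Chem.CombineMols(combined, m)
            with rdBase.BlockLogs():
                block = Chem.MolToMolBlock(combined, kekulize=True)
            props = {"compound_name": rec.name}
            if rec.cas is not None:
                props["cas"] = rec.cas
            if any(p is not None for p in rec.percentages):
                props[PERCENTAGE_TAG] = " ".join(
                    "-" if p is None else repr(p) for p in rec.percentages)
            write_sdf_record(fh, block, props)
    manifest = {
        "spec": asdict(spec),
        "records": [{"name": r.name, "n_components": len(r.smiles),
                     "keys": r.keys, "cas": r.cas} for r in records],
    }
    with open(out_path + ".manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return records
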