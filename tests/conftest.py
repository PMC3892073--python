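import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # oracle_utils

from chemreg import CompoundDatabase, CompoundDraft
from chemreg.chem import parse_structure
from chemreg.fixtures import FixtureSpec, gen_molecules


@pytest.fixture
def db():
    database = CompoundDatabase(":memory:").init()
    yield database
    database.close()


def make_db():
    return CompoundDatabase(":memory:").init()


def fixture_components(n_compounds=100, max_heavy=14, seed=0):
    """Single-component parsed molecules drawn from the synthetic
    generator (duplicates removed, order deterministic)."""
    records = gen_molecules(FixtureSpec(
        n_compounds=n_compounds, mixture_fraction=0.0,
        max_heavy_atoms=max_heavy, seed=seed))
    seen, mols = set(), []
    for rec in records:
        smiles = rec.smiles[0]
        if smiles not in seen:
            seen.add(smiles)
            mols.append(parse_structure(smiles))
    return mols


def populate(database, records, actor="fixture"):
    """Save generator records as compounds; returns list of ids."""
    ids = []
    for rec in records:
        draft = CompoundDraft(
            compositions=list(zip(rec.smiles, rec.percentages)),
            compound_name=rec.name, cas=rec.cas)
        outcome = database.save_compound(draft, actor=actor)
        ids.append(outcome.record["id"])
    return ids
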