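"""Service-layer behaviour: dedup, immutability, locking, hooks."""

import pytest

from chemreg import CompoundDraft, ContainableDraft, ContainerDraft
from chemreg.errors import (ConcurrentModificationError, ConstraintError,
                            NotFoundError, UniquenessError)


def _counts(db):
    return {t: s["rows"] for t, s in db.stats().items()}


class TestStructureDedup:
    def test_second_compound_reuses_structure(self, db):
        db.save_compound(CompoundDraft(compositions=[("CCO", None)],
                                       compound_name="a"), "t")
        before = _counts(db)["structures"]
        out = db.save_compound(CompoundDraft(compositions=[("OCC", None)],
                                             compound_name="b"), "t")
        assert out.structures_reused == 1
        assert out.structures_created == 0
        assert _counts(db)["structures"] == before

    def test_salt_text_expands_to_two_compositions(self, db):
        out = db.save_compound(CompoundDraft(
            compositions=[("[NH+]1=CC=CC=C1.[Br-]", None)],
            compound_name="pyridinium bromide"), "t")
        comps = out.record["compositions"]
        assert len(comps) == 2
        assert all(c["percentage"] is None for c in comps)

    def test_double_salt_collapses_repeated_counter_ion(self, db):
        """A di-cation with two identical counter-ions is stored as a
        mixture of the two distinct structures."""
        out = db.save_compound(CompoundDraft(
            compositions=[("[NH+]1=CC=[NH+]C=C1.[Br-].[Br-]", None)],
            compound_name="double salt"), "t")
        assert len(out.record["compositions"]) == 2
        assert out.structures_created + out.structures_reused == 2
        assert _counts(db)["structures"] == 2

    def test_idempotent_dedup_counts(self, db):
        draft = CompoundDraft(compositions=[("CCO", 60.0),
                                            ("c1ccccc1", 40.0)],
                              compound_name="mix")
        db.save_compound(draft, "t")
        before = _counts(db)["structures"]
        out = db.save_compound(draft, "t")
        assert out.structures_created == 0
        assert out.structures_reused == 2
        assert _counts(db)["structures"] == before
        assert _counts(db)["compound_compound"] == 2


class TestOptimisticLocking:
    def test_version_starts_at_zero_and_increments(self, db):
        out = db.save_compound(CompoundDraft(compositions=[("CCO", None)],
                                             compound_name="x"), "t")
        assert out.record["version"] == 0
        draft = CompoundDraft(compositions=[("CCO", None)],
                              compound_name="x2", id=out.record["id"],
                              expected_version=0)
        out2 = db.update_compound(draft, "t")
        assert out2.record["version"] == 1
        assert out2.record["compound_name"] == "x2"

    def test_stale_version_rejected(self, db):
        out = db.save_compound(CompoundDraft(compositions=[("CCO", None)]),
                               "t")
        draft = CompoundDraft(compositions=[("CCO", None)],
                              id=out.record["id"], expected_version=0)
        db.update_compound(draft, "t")
        with pytest.raises(ConcurrentModificationError):
            db.update_compound(draft, "t")  # still expects version 0

    def test_update_unknown_compound(self, db):
        with pytest.raises(NotFoundError):
            db.update_compound(CompoundDraft(compositions=[("C", None)],
                                             id=999, expected_version=0),
                               "t")


class TestStructureImmutability:
    def test_edit_leaves_old_structure_row_unchanged(self, db):
        out = db.save_compound(CompoundDraft(compositions=[("CCO", None)],
                                             compound_name="x"), "t")
        old_row = dict(db.store.conn.execute(
            "SELECT * FROM structures").fetchone())
        draft = CompoundDraft(compositions=[("CCN", None)],
                              compound_name="x", id=out.record["id"],
                              expected_version=0)
        out2 = db.update_compound(draft, "t")
        keys = {c["structure_key"] for c in out2.record["compositions"]}
        assert "LFQSCWFLJHTTHZ-UHFFFAOYSA-N" not in keys  # now CCN
        same_row = dict(db.store.conn.execute(
            "SELECT * FROM structures WHERE id = ?",
            (old_row["id"],)).fetchone())
        assert same_row == old_row

    def test_structure_rows_grow_monotonically(self, db):
        texts = ["CCO", "CCN", "CCO", "c1ccccc1", "OCC"]
        seen_counts = []
        for text in texts:
            db.save_compound(CompoundDraft(compositions=[(text, None)]),
                             "t")
            seen_counts.append(_counts(db)["structures"])
        assert seen_counts == sorted(seen_counts)
        assert seen_counts[-1] == 3  # three distinct keys introduced


class TestReplaceStructure:
    def test_affects_all_referencing_compositions(self, db):
        for name in ("a", "b"):
            db.save_compound(CompoundDraft(compositions=[("CCO", None)],
                                           compound_name=name), "t")
        key = db.get_compound(1)["compositions"][0]["structure_key"]
        affected = db.replace_structure(key, "CCN", "t")
        assert affected == 2
        for cid in (1, 2):
            texts = [c["structure_text"] for c in
                     db.get_compound(cid)["compositions"]]
            assert texts == ["CCN"]
        # the old row remains
        assert db.store.conn.execute(
            "SELECT COUNT(*) FROM structures WHERE structure_key = ?",
            (key,)).fetchone()[0] == 1

    def test_replace_to_existing_key_reuses_row(self, db):
        db.save_compound(CompoundDraft(compositions=[("CCO", None)]), "t")
        db.save_compound(CompoundDraft(compositions=[("CCN", None)]), "t")
        key = db.get_compound(1)["compositions"][0]["structure_key"]
        db.replace_structure(key, "NCC", "t")
        assert _counts(db)["structures"] == 2  # no duplicate created

    def test_unknown_key(self, db):
        with pytest.raises(NotFoundError):
            db.replace_structure("NOPE", "CCO", "t")


class TestContainersAndContainables:
    def _setup(self, db):
        out = db.save_compound(CompoundDraft(compositions=[("CCO", None)]),
                               "t")
        batch = db.save_containable(
            ContainableDraft(compound_id=out.record["id"]), "t")
        return batch.record["id"]

    def test_fresh_barcode_persisted(self, db):
        bid = self._setup(db)
        rec = db.save_container(ContainerDraft("BC-001", "batch", bid), "t")
        assert rec["version"] == 0

    def test_duplicate_barcode(self, db):
        bid = self._setup(db)
        db.save_container(ContainerDraft("BC-001", "batch", bid), "t")
        with pytest.raises(UniquenessError):
            db.save_container(ContainerDraft("BC-001", "batch", bid), "t")

    def test_null_barcode(self, db):
        bid = self._setup(db)
        with pytest.raises(ConstraintError):
            db.save_container(ContainerDraft(None, "batch", bid), "t")

    def test_containable_requires_existing_compound(self, db):
        with pytest.raises(NotFoundError):
            db.save_containable(ContainableDraft(compound_id=42), "t")


class TestPreSaveHooks:
    def test_hook_runs_on_create_and_update(self, db):
        db.register_pre_save_hook(
            "compound",
            lambda d: (setattr(d, "compound_name",
                               (d.compound_name or "").upper()) or d))
        out = db.save_compound(CompoundDraft(compositions=[("CCO", None)],
                                             compound_name="ethanol"), "t")
        assert out.record["compound_name"] == "ETHANOL"
        draft = CompoundDraft(compositions=[("CCO", None)],
                              compound_name="spirit", id=out.record["id"],
                              expected_version=0)
        assert db.update_compound(draft, "t").record[
            "compound_name"] == "SPIRIT"

    def test_no_hook_is_identity(self, db):
        out = db.save_compound(CompoundDraft(compositions=[("CCO", None)],
                                             compound_name="ethanol"), "t")
        assert out.record["compound_name"] == "ethanol"

    def test_raising_hook_aborts_transactionally(self, db):
        def bomb(draft):
            raise RuntimeError("boom")
        db.register_pre_save_hook("compound", bomb)
        before = _counts(db)
        with pytest.raises(RuntimeError):
            db.save_compound(CompoundDraft(compositions=[("CCO", None)]),
                             "t")
        assert _counts(db) == before


class TestAtomicity:
    def test_mid_save_failure_rolls_back_everything(self, db):
        """A constraint failure on the composition insert (after compound
        and structure rows were written in the same transaction) leaves
        every table at its prior state."""
        before = _counts(db)
        with pytest.raises(ConstraintError):
            db.save_compound(CompoundDraft(
                compositions=[("CCO", 150.0)]), "t")  # percentage > 100
        assert _counts(db) == before


class TestUniquenessPolicies:
    def test_default_permissive(self, db):
        draft = CompoundDraft(compositions=[("CCO", None)], cas="64-17-5")
        db.save_compound(draft, "t")
        db.save_compound(draft, "t")  # duplicates allowed
        assert _counts(db)["compound_compound"] == 2

    def test_by_cas(self, db):
        db.set_uniqueness_policy("by_cas")
        db.save_compound(CompoundDraft(compositions=[("CCO", None)],
                                       cas="64-17-5"), "t")
        with pytest.raises(UniquenessError):
            db.save_compound(CompoundDraft(compositions=[("CCN", None)],
                                           cas="64-17-5"), "t")
        db.save_compound(CompoundDraft(compositions=[("CCN", None)],
                                       cas=None), "t")  # null ok

    def test_by_exact_composition(self, db):
        db.set_uniqueness_policy("by_exact_composition")
        db.save_compound(CompoundDraft(compositions=[("CCO", 50.0),
                                                     ("c1ccccc1", 50.0)]),
                         "t")
        with pytest.raises(UniquenessError):
            db.save_compound(CompoundDraft(
                compositions=[("c1ccccc1", 10.0), ("OCC", 90.0)]), "t")
        db.save_compound(CompoundDraft(compositions=[("CCO", None)]), "t")
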