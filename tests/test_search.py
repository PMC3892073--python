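"""Search semantics: mixtures, distinct, paging, counts, planner."""

import pytest

from chemreg import (CompoundDraft, ContainableDraft, ContainerDraft,
                     SearchRequest, StructureQuery)
from chemreg.errors import UnknownFieldError

from conftest import fixture_components, make_db, populate
from chemreg.fixtures import FixtureSpec, gen_molecules


def sub(query, **kw):
    return SearchRequest(target="compound",
                         structure=StructureQuery(mode="sub",
                                                  query_text=query), **kw)


@pytest.fixture
def mixture_db(db):
    db.save_compound(CompoundDraft(compositions=[("CCCCCC", None)],
                                   compound_name="hexane"), "t")
    db.save_compound(CompoundDraft(compositions=[("CCO", None)],
                                   compound_name="ethanol"), "t")
    db.save_compound(CompoundDraft(
        compositions=[("c1ccccc1", 50.0), ("Cc1ccccc1", 50.0)],
        compound_name="M"), "t")
    return db


class TestMixtureSemantics:
    def test_distinct_returns_mixture_once(self, mixture_db):
        page = mixture_db.search(sub("c1ccccc1", distinct=True))
        assert page.total_count == 1
        assert [i["compound_name"] for i in page.items] == ["M"]

    def test_non_distinct_one_row_per_component(self, mixture_db):
        page = mixture_db.search(sub("c1ccccc1", distinct=False))
        assert page.total_count == 2
        assert {i["compound_name"] for i in page.items} == {"M"}
        assert len({i["matched_structure_id"] for i in page.items}) == 2

    def test_exact_search_on_one_ion_returns_salt(self, mixture_db):
        mixture_db.save_compound(CompoundDraft(
            compositions=[("[NH+]1=CC=CC=C1.[Br-]", None)],
            compound_name="salt"), "t")
        req = SearchRequest(target="compound",
                            structure=StructureQuery(mode="exact",
                                                     query_text="[Br-]"))
        page = mixture_db.search(req)
        assert [i["compound_name"] for i in page.items] == ["salt"]

    def test_similarity_identity_finds_exactly_ethanol(self, mixture_db):
        req = SearchRequest(
            target="compound",
            structure=StructureQuery(mode="similarity", query_text="CCO",
                                     min_score=1.0))
        page = mixture_db.search(req)
        assert [i["compound_name"] for i in page.items] == ["ethanol"]

    def test_formula_search(self, mixture_db):
        req = SearchRequest(target="compound",
                            structure=StructureQuery(mode="formula",
                                                     query_text="C6H6"))
        page = mixture_db.search(req, None)
        assert [i["compound_name"] for i in page.items] == ["M"]

    def test_mw_range_bounds_matching_component(self, mixture_db):
        req = sub("c1ccccc1")
        req.structure.mw_min = 80.0  # benzene (78.11) excluded, toluene in
        page = mixture_db.search(req, None)
        assert page.total_count == 1


class TestPaging:
    def test_page_arithmetic(self, db):
        for i in range(5):
            db.save_compound(CompoundDraft(
                compositions=[("C" * (i + 1), None)],
                compound_name=f"c{i}"), "t")
        req = sub("C", page_size=4)
        p0 = db.search(req)
        req1 = sub("C", page_size=4, page_index=1)
        p1 = db.search(req1)
        assert len(p0.items) == 4 and len(p1.items) == 1
        assert p0.total_count == p1.total_count == 5

    def test_concatenated_pages_equal_unpaged(self, db):
        records = gen_molecules(FixtureSpec(n_compounds=60, seed=21))
        populate(db, records)
        unpaged = db.search(sub("C", page_size=10 ** 6)).items
        collected = []
        page_index = 0
        while True:
            page = db.search(sub("C", page_size=7, page_index=page_index))
            if not page.items:
                break
            collected.extend(page.items)
            page_index += 1
        assert [i["id"] for i in collected] == [i["id"] for i in unpaged]
        assert len({i["id"] for i in collected}) == len(collected)

    def test_default_sort_is_deterministic(self, db):
        for name in ("b", "a", "c"):
            db.save_compound(CompoundDraft(compositions=[("CCO", None)],
                                           compound_name=name), "t")
        page = db.search(sub("CCO", sort=[("compound_name", "desc")]))
        assert [i["compound_name"] for i in page.items] == ["c", "b", "a"]


class TestCountCache:
    def test_count_computed_once_across_pages(self, db):
        for i in range(6):
            db.save_compound(CompoundDraft(
                compositions=[("C" * (i + 1), None)]), "t")
        svc = db.search_service
        svc.count_computations = 0
        p0 = db.search(sub("C", page_size=2, page_index=0))
        p1 = db.search(sub("C", page_size=2, page_index=1))
        p2 = db.search(sub("C", page_size=2, page_index=2))
        assert svc.count_computations == 1
        assert not p0.count_from_cache
        assert p1.count_from_cache and p2.count_from_cache
        assert p0.total_count == p1.total_count == p2.total_count == 6

    def test_write_invalidates_cache(self, db):
        db.save_compound(CompoundDraft(compositions=[("CCO", None)]), "t")
        total, cached = db.count(sub("C"))
        assert (total, cached) == (1, False)
        assert db.count(sub("C"))[1] is True
        db.save_compound(CompoundDraft(compositions=[("CC", None)]), "t")
        total, cached = db.count(sub("C"))
        assert (total, cached) == (2, False)

    def test_distinct_count_bounded_by_non_distinct(self, db):
        records = gen_molecules(FixtureSpec(n_compounds=40,
                                            mixture_fraction=0.4, seed=3))
        populate(db, records)
        for query in ("C", "c1ccccc1", "O", "N"):
            d = db.count(sub(query, distinct=True))[0]
            nd = db.count(sub(query, distinct=False))[0]
            assert d <= nd


class TestDistinctDefault:
    def test_default_off_single_component_identical(self, db):
        for i in range(5):
            db.save_compound(CompoundDraft(
                compositions=[("C" * (i + 1) + "O", None)]), "t")
        db.set_distinct_default(False)
        off = [i["id"] for i in db.search(sub("C", page_size=100)).items]
        on = [i["id"] for i in
              db.search(sub("C", page_size=100, distinct=True)).items]
        assert off == on

    def test_default_off_mixture_duplicates_appear(self, mixture_db):
        mixture_db.set_distinct_default(False)
        page = mixture_db.search(sub("c1ccccc1"))
        assert page.total_count == 2

    def test_per_request_overrides_default(self, mixture_db):
        mixture_db.set_distinct_default(False)
        page = mixture_db.search(sub("c1ccccc1", distinct=True))
        assert page.total_count == 1


class TestPlanner:
    @pytest.fixture
    def stocked(self, db):
        records = gen_molecules(FixtureSpec(n_compounds=300, seed=13,
                                            name_prefix="ZINC"))
        populate(db, records)
        return db

    def test_selective_prefix_filter_goes_property_first(self, stocked):
        req = sub("C", filters=[("compound_name", "like-prefix",
                                 "ZINC00001")])
        decision = stocked.search_service.plan(req, stocked.stats())
        assert decision.strategy == "PROPERTY_FIRST"
        assert decision.estimated_candidates <= 0.05 * 300

    def test_no_filter_forces_index_screen(self, stocked):
        decision = stocked.search_service.plan(sub("C"), stocked.stats())
        assert decision.strategy == "INDEX_SCREEN"

    def test_unselective_filter_stays_index_screen(self, stocked):
        req = sub("C", filters=[("compound_name", "like-prefix", "ZINC")])
        decision = stocked.search_service.plan(req, stocked.stats())
        assert decision.strategy == "INDEX_SCREEN"

    def test_both_strategies_identical_hit_sets(self, stocked):
        svc = stocked.search_service
        for query in ("C", "c1ccccc1", "CCO", "C1CCCCC1"):
            for prefix in ("ZINC0000", "ZINC00001", "ZINC000111"):
                req = sub(query, page_size=10 ** 6,
                          filters=[("compound_name", "like-prefix",
                                    prefix)])
                svc.tau = 1.0  # force PROPERTY_FIRST eligibility
                svc.n_max = 10 ** 9
                pf = {i["id"] for i in stocked.search(req).items}
                assert svc.last_plan.strategy == "PROPERTY_FIRST"
                svc.tau = -1.0  # force INDEX_SCREEN
                isc = {i["id"] for i in stocked.search(req).items}
                assert svc.last_plan.strategy == "INDEX_SCREEN"
                assert pf == isc
        svc.tau = 0.05
        svc.n_max = 5000

    def test_property_first_verifies_at_most_candidates(self, stocked):
        svc = stocked.search_service
        svc.tau = 1.0
        svc.n_max = 10 ** 9
        req = sub("c1ccccc1", filters=[("compound_name", "like-prefix",
                                        "ZINC00001")])
        candidates = stocked.store.conn.execute(
            "SELECT COUNT(*) FROM composition_compound c JOIN "
            "compound_compound k ON k.id = c.compound_id "
            "WHERE k.compound_name LIKE 'ZINC00001%'").fetchone()[0]
        svc.verifications = 0
        stocked.search(req)
        assert svc.verifications <= candidates


class TestFindByCasAndFilters:
    def test_find_by_cas_not_unique(self, db):
        for name in ("a", "b"):
            db.save_compound(CompoundDraft(compositions=[("CCO", None)],
                                           compound_name=name,
                                           cas="64-17-5"), "t")
        db.save_compound(CompoundDraft(compositions=[("CCN", None)],
                                       compound_name="c", cas=None), "t")
        hits = db.find_by_cas("64-17-5")
        assert [h["compound_name"] for h in hits] == ["a", "b"]
        assert db.find_by_cas("1-11-1") == []

    def test_unknown_field_raises(self, db):
        with pytest.raises(UnknownFieldError):
            db.search(SearchRequest(target="compound",
                                    filters=[("nope", "eq", 1)]))

    def test_eq_and_range_filters(self, db):
        for i, name in enumerate(("a", "b", "c")):
            db.save_compound(CompoundDraft(compositions=[("CCO", None)],
                                           compound_name=name), "t")
        page = db.search(SearchRequest(
            target="compound", filters=[("compound_name", "eq", "b")]))
        assert [i["compound_name"] for i in page.items] == ["b"]
        page = db.search(SearchRequest(
            target="compound", filters=[("id", "range", (2, None))]))
        assert [i["id"] for i in page.items] == [2, 3]


class TestContainerSearch:
    def test_structure_search_reaches_containers(self, db):
        out = db.save_compound(CompoundDraft(compositions=[("CCO", None)],
                                             compound_name="ethanol"), "t")
        batch = db.save_containable(
            ContainableDraft(compound_id=out.record["id"]), "t")
        db.save_container(
            ContainerDraft("BC-1", "batch", batch.record["id"]), "t")
        req = SearchRequest(target="container",
                            structure=StructureQuery(mode="sub",
                                                     query_text="CO"))
        page = db.search(req)
        assert [i["barcode"] for i in page.items] == ["BC-1"]

    def test_barcode_filter_unique_hit(self, db):
        out = db.save_compound(CompoundDraft(compositions=[("CCO", None)]),
                               "t")
        bid = db.save_containable(
            ContainableDraft(compound_id=out.record["id"]),
            "t").record["id"]
        for code in ("BC-1", "BC-2"):
            db.save_container(ContainerDraft(code, "batch", bid), "t")
        page = db.search(SearchRequest(
            target="container", filters=[("barcode", "eq", "BC-2")]))
        assert len(page.items) == 1
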