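"""Quick search, predicate trees, sorting, pagination, oracle agreement."""
import itertools
import random

import pytest

from chemvault import auth, fixtures, query, store
from chemvault.model import EditMeta, Role, UserSrv
from chemvault.query import (
    And, CasQuery, IdSet, Leaf, LinkPred, NumericPred, Or, Paging, RegexQuery,
    SortSpec, StructurePred, TextPred,
)
from chemvault.store import ChangeRecord

from conftest import molblock
from oracles import naive_hitset


def admin():
    return UserSrv(
        id=1, alias="root", password_hash="pbkdf2$1$00$00", role=Role.ADMIN,
        projects=set(), created=EditMeta(ts=1, user=1),
    )


def build_tree(recs):
    res = store.replay(
        [ChangeRecord(seq=i + 1, ts=i + 1, user=1, **r) for i, r in enumerate(recs)]
    )
    assert res.is_ok, res.error
    return res.value


@pytest.fixture(scope="module")
def lab_tree():
    """Benzene/toluene/cyclohexane plus a structure-less compound."""
    return build_tree(
        [
            dict(family="project", id=1, op="add", payload={"name": "Alpha", "owner": 1}),
            dict(family="project", id=2, op="add", payload={"name": "Beta", "owner": 1}),
            dict(family="location", id=1, op="add", payload={"name": "L1"}),
            dict(family="supplier", id=1, op="add", payload={"name": "S1"}),
            dict(family="method", id=1, op="add", payload={"name": "IC50"}),
            dict(family="compound", id=1, op="add",
                 payload={"name": "benzenol", "casNr": "71-43-2",
                          "structure": molblock("c1ccccc1"), "project": 1}),
            dict(family="compound", id=2, op="add",
                 payload={"name": "toluene", "structure": molblock("Cc1ccccc1"), "project": 1}),
            dict(family="compound", id=3, op="add",
                 payload={"name": "cyclohexane", "structure": molblock("C1CCCCC1"), "project": 2}),
            dict(family="compound", id=4, op="add",
                 payload={"name": "mystery", "project": 1}),
            dict(family="container", id=1, op="add",
                 payload={"compound": 1, "batch": "BATCH-A", "location": 1, "supplier": 1,
                          "amount": 5.0, "purity": 99.0, "project": 1}),
            dict(family="container", id=2, op="add",
                 payload={"compound": 2, "batch": "BATCH-B", "location": 1, "supplier": 1,
                          "amount": 250.0, "purity": 80.0, "project": 1}),
            dict(family="biodata", id=1, op="add",
                 payload={"container": 1, "method": 1, "value": 42.0, "unit": "uM", "project": 1}),
        ]
    )


class TestParseQuick:
    @pytest.mark.parametrize(
        "s,expected",
        [
            ("12 77 103", IdSet(frozenset({12, 77, 103}))),
            ("71-43-2", CasQuery("71-43-2")),
            ("amino.*benzo", RegexQuery("amino.*benzo")),
            ("7", IdSet(frozenset({7}))),
        ],
    )
    def test_dispatch_precedence(self, s, expected):
        assert query.parse_quick(s).value == expected

    def test_invalid_regex_reported(self):
        res = query.parse_quick("ami(no")
        assert res.is_err and res.error.code == "bad_regex"


class TestCompileAndRun:
    def run_ids(self, tree, q, user=None):
        res = query.query_hits(tree, user or admin(), q)
        assert res.is_ok, getattr(res, "error", None)
        return {c.id for c in res.value}

    def test_numeric_leaf_filters_by_mass(self, lab_tree):
        q = Leaf("compound.mass", NumericPred((("<=", 80.0),)))
        assert self.run_ids(lab_tree, q) == {1}  # benzene 78.11; toluene 92.1

    def test_and_is_hitset_intersection(self, lab_tree):
        name_leaf = Leaf("compound.name", TextPred("contains", "ol"))
        proj_leaf = Leaf("compound.project", LinkPred(frozenset({1})))
        both = self.run_ids(lab_tree, And((name_leaf, proj_leaf)))
        assert both == self.run_ids(lab_tree, name_leaf) & self.run_ids(lab_tree, proj_leaf)

    def test_unknown_field_rejected(self):
        res = query.compile_tree(Leaf("compound.colour", TextPred("exact", "x")))
        assert res.is_err and res.error.code == "unknown_field"

    def test_empty_and_matches_all_empty_or_none(self, lab_tree):
        assert self.run_ids(lab_tree, And(())) == {1, 2, 3, 4}
        assert self.run_ids(lab_tree, Or(())) == set()

    def test_substructure_leaf(self, lab_tree):
        q = Leaf("compound.structure", StructurePred("substructure", molblock("c1ccccc1")))
        assert self.run_ids(lab_tree, q) == {1, 2}  # aromatic ring: benzene + toluene

    def test_similarity_leaf_threshold(self, lab_tree):
        q = Leaf("compound.structure",
                 StructurePred("similarity", molblock("c1ccccc1"), threshold=0.999))
        assert self.run_ids(lab_tree, q) == {1}

    def test_structureless_compounds_skipped_not_errored(self, lab_tree):
        q = Leaf("compound.structure", StructurePred("substructure", molblock("C")))
        assert 4 not in self.run_ids(lab_tree, q)

    def test_container_leaf_any_quantified(self, lab_tree):
        q = Leaf("container.amount", NumericPred(((">=", 100.0),)))
        assert self.run_ids(lab_tree, q) == {2}

    def test_biodata_leaf(self, lab_tree):
        q = Leaf("biodata.value", NumericPred((("==", 42.0),)))
        assert self.run_ids(lab_tree, q) == {1}

    def test_visibility_precedes_matching(self, lab_tree):
        restricted = UserSrv(
            id=2, alias="u", password_hash="pbkdf2$1$00$00", role=Role.COMMON,
            projects={1}, created=EditMeta(ts=1, user=1),
        )
        q = Leaf("compound.name", TextPred("contains", "cyclo"))
        assert self.run_ids(lab_tree, q) == {3}
        assert self.run_ids(lab_tree, q, user=restricted) == set()

    def test_quick_regex_reaches_batch_and_cas(self, lab_tree):
        assert self.run_ids(lab_tree, RegexQuery("BATCH-B")) == {2}
        assert self.run_ids(lab_tree, CasQuery("71-43-2")) == {1}
        assert self.run_ids(lab_tree, IdSet(frozenset({2, 4}))) == {2, 4}


class TestHitsetAlgebra:
    def test_connectives_invariant_under_child_permutation(self, lab_tree):
        rng = random.Random(11)
        leaves = [
            Leaf("compound.name", TextPred("contains", "e")),
            Leaf("compound.mass", NumericPred(((">", 50.0),))),
            Leaf("container.purity", NumericPred(((">=", 90.0),))),
        ]
        for connective in (And, Or):
            base = {c.id for c in query.query_hits(lab_tree, admin(), connective(tuple(leaves))).value}
            for _ in range(4):
                shuffled = leaves[:]
                rng.shuffle(shuffled)
                got = {
                    c.id
                    for c in query.query_hits(lab_tree, admin(), connective(tuple(shuffled))).value
                }
                assert got == base

    def test_idempotent_children(self, lab_tree):
        leaf = Leaf("compound.name", TextPred("contains", "e"))
        one = {c.id for c in query.query_hits(lab_tree, admin(), And((leaf,))).value}
        dup = {c.id for c in query.query_hits(lab_tree, admin(), And((leaf, leaf))).value}
        assert one == dup


class TestOracleAgreement:
    def test_random_trees_match_naive_filter(self):
        data = fixtures.gen_dataset(fixtures.FixtureSpec(seed=99, n_compounds=40))
        compounds = sorted(data.tree.alive("compound"), key=lambda c: c.id)
        for seed in range(25):
            qt = fixtures.gen_query(seed, depth=random.Random(seed).randint(1, 3))
            engine = query.query_hits(data.tree, admin(), qt)
            assert engine.is_ok
            assert {c.id for c in engine.value} == naive_hitset(qt, compounds, data.tree)


class TestSortHits:
    def get(self, tree, sort):
        hits = query.query_hits(tree, admin(), None).value
        return query.sort_hits(hits, sort).value

    def test_ascending_by_mass(self, lab_tree):
        ordered = self.get(lab_tree, SortSpec("compound.mass", ascending=True))
        masses = [query._compound_mass(c) for c in ordered if c.structure]
        assert masses == sorted(masses)

    def test_missing_field_last_in_both_directions(self, lab_tree):
        for asc in (True, False):
            ordered = self.get(lab_tree, SortSpec("compound.mass", ascending=asc))
            assert ordered[-1].id == 4  # the structure-less compound

    def test_stability_on_equal_keys(self):
        tree = build_tree(
            [dict(family="project", id=1, op="add", payload={"name": "P", "owner": 1})]
            + [
                dict(family="compound", id=i, op="add",
                     payload={"name": "same", "project": 1})
                for i in (1, 2, 3)
            ]
        )
        ordered = self.get(tree, SortSpec("compound.name"))
        assert [c.id for c in ordered] == [1, 2, 3]

    def test_unsortable_field_rejected(self, lab_tree):
        hits = query.query_hits(lab_tree, admin(), None).value
        res = query.sort_hits(hits, SortSpec("compound.structure"))
        assert res.is_err and res.error.code == "unsortable_field"


class TestPaginate:
    def test_slices_and_total(self):
        hits = list(range(25))
        assert (len(query.paginate(hits, Paging(0, 10)).items),
                query.paginate(hits, Paging(0, 10)).total) == (10, 25)
        assert len(query.paginate(hits, Paging(20, 10)).items) == 5
        assert query.paginate(hits, Paging(30, 10)).items == []

    def test_pages_partition_hitset(self):
        rng = random.Random(5)
        for _ in range(20):
            hits = [rng.randrange(10**6) for _ in range(rng.randint(0, 300))]
            limit = rng.randint(1, 50)
            pages = [
                query.paginate(hits, Paging(off, limit))
                for off in range(0, max(len(hits), 1), limit)
            ]
            glued = list(itertools.chain.from_iterable(p.items for p in pages))
            assert glued == hits
            assert all(p.total == len(hits) for p in pages)

    def test_bad_paging_rejected(self):
        with pytest.raises(query.QueryErr):
            Paging(-1, 10)
        with pytest.raises(query.QueryErr):
            Paging(0, 0)


class TestWireSchema:
    def test_tree_json_round_trip(self):
        qt = And((
            Leaf("compound.mass", NumericPred((("<=", 300.0), (">", 10.0)))),
            Or((
                Leaf("compound.name", TextPred("regex", "CMP-\\d+")),
                Leaf("compound.structure", StructurePred("similarity", molblock("CCO"), 0.5)),
                Leaf("container.supplier", LinkPred(frozenset({1, 3}))),
            )),
        ))
        assert query.tree_from_json(query.tree_to_json(qt)) == qt
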