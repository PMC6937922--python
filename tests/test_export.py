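"""Export: row explosion, SDF/CSV writers, biodata aggregation."""
import random

import pytest

from chemvault import chem, export, fixtures, store
from chemvault.export import ExportSpec
from chemvault.model import BiodataSrv, EditMeta
from chemvault.store import ChangeRecord

from conftest import molblock

META = EditMeta(ts=1, user=1)


def build_tree(recs):
    res = store.replay(
        [ChangeRecord(seq=i + 1, ts=i + 1, user=1, **r) for i, r in enumerate(recs)]
    )
    assert res.is_ok, res.error
    return res.value


@pytest.fixture(scope="module")
def lab():
    """2 structured compounds (2 and 1 containers), 1 with zero containers."""
    tree = build_tree(
        [
            dict(family="project", id=1, op="add", payload={"name": "P", "owner": 1}),
            dict(family="location", id=1, op="add", payload={"name": "L"}),
            dict(family="supplier", id=1, op="add", payload={"name": "S"}),
            dict(family="method", id=1, op="add", payload={"name": "IC50"}),
            dict(family="compound", id=1, op="add",
                 payload={"name": "benzene", "structure": molblock("c1ccccc1"), "project": 1}),
            dict(family="compound", id=2, op="add",
                 payload={"name": "tolu\tene", "structure": molblock("Cc1ccccc1"), "project": 1}),
            dict(family="compound", id=3, op="add", payload={"name": "bare", "project": 1}),
            dict(family="container", id=1, op="add",
                 payload={"compound": 1, "batch": "B1", "location": 1, "supplier": 1,
                          "amount": 1.5, "project": 1}),
            dict(family="container", id=2, op="add",
                 payload={"compound": 1, "batch": "B2", "location": 1, "supplier": 1, "project": 1}),
            dict(family="container", id=3, op="add",
                 payload={"compound": 2, "batch": "B3", "location": 1, "supplier": 1, "project": 1}),
            dict(family="biodata", id=1, op="add",
                 payload={"container": 1, "method": 1, "value": 1.0, "project": 1}),
            dict(family="biodata", id=2, op="add",
                 payload={"container": 1, "method": 1, "value": 3.0, "project": 1}),
        ]
    )
    compounds = sorted(tree.alive("compound"), key=lambda c: c.id)
    return tree, compounds


class TestBuildRows:
    def test_compound_only_fields_one_row_per_compound(self, lab):
        tree, compounds = lab
        rows = export.build_rows(compounds, tree, ExportSpec(fields=["compound.name"])).value
        assert len(rows) == 3

    def test_container_field_one_row_per_container(self, lab):
        tree, compounds = lab
        spec = ExportSpec(fields=["compound.name", "container.batch"])
        rows = export.build_rows(compounds, tree, spec).value
        assert len(rows) == 3  # containers: 2 + 1 + 0
        assert [r[1] for r in rows] == ["B1", "B2", "B3"]
        assert rows[0][0] == rows[1][0] == "benzene"  # compound values repeated

    def test_zero_container_compound_contributes_nothing_in_container_mode(self, lab):
        tree, compounds = lab
        spec = ExportSpec(fields=["container.batch"])
        rows = export.build_rows([compounds[2]], tree, spec).value
        assert rows == []

    def test_unknown_field_rejected(self, lab):
        with pytest.raises(Exception):
            ExportSpec(fields=["compound.flavour"])

    def test_biodata_aggregate_column_triggers_container_mode(self, lab):
        tree, compounds = lab
        spec = ExportSpec(fields=["compound.name", "biodata.mean:1", "biodata.count:1"])
        rows = export.build_rows(compounds, tree, spec).value
        assert len(rows) == 3
        by_name = {(r[0], r[1], r[2]) for r in rows}
        assert ("benzene", 2.0, 2) in by_name  # container 1: values 1, 3
        assert ("benzene", None, None) in by_name  # container 2: no entries

    def test_column_conservation(self, lab):
        tree, compounds = lab
        rng = random.Random(2)
        pool = ["compound.name", "compound.casNr", "compound.mass",
                "container.batch", "container.amount", "biodata.max:1"]
        for _ in range(10):
            fields = rng.sample(pool, rng.randint(1, len(pool)))
            rows = export.build_rows(compounds, tree, ExportSpec(fields=fields)).value
            assert all(len(r) == len(fields) for r in rows)


class TestWriteSdf:
    def test_grammar_one_record(self, lab):
        tree, compounds = lab
        spec = ExportSpec(fields=["compound.name"], format="sdf")
        text = export.write_sdf([compounds[0]], tree, spec).value
        assert text.count("$$$$") == 1
        assert "> <compound.name>\nbenzene" in text
        assert "V2000" in text

    def test_record_count_matches_rows(self, lab):
        tree, compounds = lab
        spec = ExportSpec(fields=["compound.name"], format="sdf")
        text = export.write_sdf(compounds, tree, spec).value
        assert text.count("$$$$") == 3

    def test_structureless_compound_gets_zero_atom_block(self, lab):
        tree, compounds = lab
        spec = ExportSpec(fields=["compound.name"], format="sdf")
        text = export.write_sdf([compounds[2]], tree, spec).value
        assert "  0  0  0  0" in text and text.count("$$$$") == 1

    def test_round_trip_preserves_graphs(self, lab):
        tree, compounds = lab
        structured = [c for c in compounds if c.structure]
        spec = ExportSpec(fields=["compound.name"], format="sdf")
        text = export.write_sdf(structured, tree, spec).value
        records = export.read_sdf(text)
        assert len(records) == len(structured)
        for (molblock_text, items), original in zip(records, structured):
            emitted = chem.parse_molfile(molblock_text)
            assert emitted.is_ok
            expected = chem.parse_molfile(original.structure).value
            assert chem.graph_signature(emitted.value) == chem.graph_signature(expected)


class TestWriteCsv:
    def test_header_plus_rows_tab_delimited(self, lab):
        tree, compounds = lab
        spec = ExportSpec(fields=["compound.id", "compound.name"])
        rows = export.build_rows(compounds, tree, spec).value
        text = export.write_csv(rows, spec)
        lines = text.splitlines()
        assert len(lines) == 4
        assert lines[0] == "compound.id\tcompound.name"

    def test_embedded_tab_quoted_and_recovered(self, lab):
        tree, compounds = lab
        spec = ExportSpec(fields=["compound.name"])
        rows = export.build_rows(compounds, tree, spec).value
        text = export.write_csv(rows, spec)
        parsed = export.read_csv(text)
        assert parsed[2] == ["tolu\tene"]

    def test_empty_hitset_gives_header_only(self, lab):
        tree, _ = lab
        spec = ExportSpec(fields=["compound.name"])
        assert export.write_csv([], spec) == "compound.name\n"


class TestAggregateBiodata:
    def entries(self, values, method=1):
        return [
            BiodataSrv(id=i + 1, container=1, method=method, value=v, project=1, created=META)
            for i, v in enumerate(values)
        ]

    def test_count_mean_min_max(self):
        stats = export.aggregate_biodata(self.entries([1.0, 2.0, 3.0]), 1)
        assert (stats.count, stats.mean, stats.min, stats.max) == (3, 2.0, 1.0, 3.0)

    def test_absent_when_method_has_no_entries(self):
        assert export.aggregate_biodata(self.entries([1.0], method=2), 1) is None
        assert export.aggregate_biodata([], 1) is None

    def test_single_value_degenerate(self):
        stats = export.aggregate_biodata(self.entries([7.5]), 1)
        assert stats.mean == stats.min == stats.max == 7.5 and stats.count == 1

    def test_other_methods_excluded(self):
        mixed = self.entries([1.0, 5.0]) + self.entries([100.0], method=2)
        stats = export.aggregate_biodata(mixed, 1)
        assert stats.max == 5.0


class TestRowCountLaw:
    def test_random_hitsets_obey_row_rule(self):
        data = fixtures.gen_dataset(fixtures.FixtureSpec(seed=31, n_compounds=30))
        rng = random.Random(31)
        compounds = sorted(data.tree.alive("compound"), key=lambda c: c.id)
        for _ in range(10):
            hitset = rng.sample(compounds, rng.randint(0, len(compounds)))
            c_rows = export.build_rows(
                hitset, data.tree, ExportSpec(fields=["compound.name"])
            ).value
            assert len(c_rows) == len(hitset)
            k_rows = export.build_rows(
                hitset, data.tree, ExportSpec(fields=["container.batch"])
            ).value
            expected = sum(
                1
                for c in hitset
                for kid in c.containers
                if data.tree.entity("container", kid) is not None
            )
            assert len(k_rows) == expected
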