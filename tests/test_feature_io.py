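import csv

import pytest
from hypothesis import given, settings, strategies as st

from phytofp.feature_io import (
    DB_SOURCES,
    DEFAULT_DIALECT,
    Dialect,
    FeatureRecord,
    OntologyError,
    TableFormatError,
    read_feature_table,
    read_ontology,
    write_feature_table,
    write_ontology,
)
from phytofp.synthetic import GeneratorSpec, build_ontology, generate_cd_table

record_strategy = st.builds(
    FeatureRecord,
    compound_name=st.one_of(st.none(), st.text(
        alphabet=st.characters(codec="ascii", exclude_characters='",\r\n'),
        min_size=1, max_size=20).filter(lambda s: s.strip())),
    formula=st.one_of(st.none(), st.from_regex(r"C[0-9]{1,2}H[0-9]{1,2}O[0-9]", fullmatch=True)),
    ion_mode=st.sampled_from(["positive", "negative"]),
    precursor_mz=st.floats(50.0, 2000.0, allow_nan=False),
    calc_mw=st.floats(50.0, 2000.0),
    rt=st.floats(0.0, 120.0),
    peak_area=st.floats(0.0, 1e10),
    db_hits=st.frozensets(st.sampled_from(DB_SOURCES)),
    has_ms2=st.booleans(),
    msi_level=st.sampled_from([1, 2, 3, 4]),
    species=st.sampled_from(["Cascara", "Senna", ""]),
    replicate_id=st.sampled_from(["R1", "R2", ""]),
)


@settings(max_examples=50, deadline=None)
@given(st.lists(record_strategy, max_size=8))
def test_write_read_roundtrip_is_identity(tmp_path_factory, records):
    """Reading back a written table reproduces every field exactly."""
    path = tmp_path_factory.mktemp("io") / "table.csv"
    write_feature_table(records, path)
    back = read_feature_table(path)
    assert back == records


def test_empty_list_writes_header_only(tmp_path):
    path = tmp_path / "empty.csv"
    write_feature_table([], path)
    lines = path.read_text().strip().splitlines()
    assert len(lines) == 1
    assert read_feature_table(path) == []


def test_write_is_byte_stable(tmp_path):
    records, _ = generate_cd_table(
        GeneratorSpec(seed=5, species=("X",), replicates_per_species=1,
                      n_compounds_per_species=500)
    )
    write_feature_table(records, tmp_path / "a.csv")
    write_feature_table(records, tmp_path / "b.csv")
    assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()


def test_vendor_ion_mode_strings_map_through_dialect(tmp_path):
    dialect = Dialect(
        columns=dict(DEFAULT_DIALECT.columns),
        ion_mode_values={"ESI+": "positive", "ESI−": "negative"},
    )
    path = tmp_path / "t.csv"
    cols = dialect.columns
    with path.open("w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(list(cols.values()) + ["Annot. Source"])
        w.writerow(["a", "", "ESI+", "100.1", "99.1", "10", "2e6", "True", "2", "S", "R1", "mzCloud"])
        w.writerow(["b", "", "ESI−", "100.1", "101.1", "10", "2e6", "True", "2", "S", "R1", ""])
    recs = read_feature_table(path, dialect)
    assert [r.ion_mode for r in recs] == ["positive", "negative"]
    assert recs[0].db_hits == frozenset({"mzCloud"})


def test_missing_mandatory_column_names_the_column(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("Name,Formula\nfoo,C6H6\n")
    with pytest.raises(TableFormatError, match="Ion Mode"):
        read_feature_table(path)


def test_unparseable_numeric_cell_reports_row(tmp_path):
    path = tmp_path / "bad.csv"
    header = ",".join(DEFAULT_DIALECT.columns.values())
    path.write_text(
        header + "\n" + "x,,positive,not-a-number,99.0,10,2e6,True,2,S,R1\n"
    )
    with pytest.raises(TableFormatError, match="row 1"):
        read_feature_table(path)


def test_generated_table_matches_ledger_counts(tmp_path):
    spec = GeneratorSpec(seed=9, species=("A", "B"), replicates_per_species=1,
                         n_compounds_per_species=100)
    records, ledger = generate_cd_table(spec)
    path = tmp_path / "gen.csv"
    write_feature_table(records, path)
    back = read_feature_table(path)
    assert len(back) == len(ledger.feature_rows)
    assert sum(r.peak_area for r in back) == pytest.approx(
        sum(r.peak_area for r in records)
    )
    assert back == records


class TestOntology:
    def test_roundtrip_and_parent_lookup(self, tmp_path):
        onto = build_ontology()
        path = tmp_path / "onto.csv"
        write_ontology(onto, path)
        back = read_ontology(path)
        assert back.superclass_parent == dict(onto.superclass_parent)
        assert back.class_parent == dict(onto.class_parent)
        assert back.pathway_of_class("Flavones") == "Shikimates and Phenylpropanoids"

    def test_study_scale_hierarchy_loads_all_superclasses(self, tmp_path):
        """The 19 superclasses seen across the four herbal drugs load as 19
        distinct entries."""
        superclasses = {
            "Flavonoids": "Shikimates and Phenylpropanoids",
            "Phenylpropanoids (C6-C3)": "Shikimates and Phenylpropanoids",
            "Polycyclic aromatic polyketides": "Polyketides",
            "Isoflavonoids": "Shikimates and Phenylpropanoids",
            "Coumarins": "Shikimates and Phenylpropanoids",
            "Diterpenoids": "Terpenoids",
            "Lignans": "Shikimates and Phenylpropanoids",
            "Benzenoids": "Shikimates and Phenylpropanoids",
            "Monoterpenoids": "Terpenoids",
            "Phloroglucinols": "Polyketides",
            "Aromatic polyketides": "Polyketides",
            "Pseudoalkaloids": "Alkaloids",
            "Stilbenoids": "Shikimates and Phenylpropanoids",
            "Tyrosine alkaloids": "Alkaloids",
            "Fatty acids and conjugates": "Fatty acids",
            "Naphthalenes": "Polyketides",
            "Phenolic acids (C6-C1)": "Shikimates and Phenylpropanoids",
            "Chromanes": "Polyketides",
            "Unclassified": "Unclassified",
        }
        path = tmp_path / "onto.csv"
        with path.open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["pathway", "superclass", "class"])
            for sc, pw in superclasses.items():
                w.writerow([pw, sc, ""])
        onto = read_ontology(path)
        assert len(onto.superclasses) == 19

    def test_empty_file_gives_empty_ontology(self, tmp_path):
        path = tmp_path / "empty.csv"
        path.write_text("")
        onto = read_ontology(path)
        assert not onto.pathways and not onto.superclasses and not onto.classes

    def test_conflicting_class_parent_rejected(self, tmp_path):
        path = tmp_path / "conflict.csv"
        path.write_text(
            "pathway,superclass,class\nP1,S1,C1\nP1,S2,C1\n"
        )
        with pytest.raises(OntologyError, match="C1"):
            read_ontology(path)

    @settings(max_examples=30, deadline=None)
    @given(st.data())
    def test_random_consistent_triples_match_brute_force(self, tmp_path_factory, data):
        """Parent lookups agree with a direct scan of the triple file."""
        n_path = data.draw(st.integers(1, 3))
        triples = []
        for ci in range(data.draw(st.integers(1, 12))):
            sc = f"S{ci % 5}"
            pw = f"P{(ci % 5) % n_path}"  # superclass's pathway fixed by its id
            triples.append((pw, sc, f"C{ci}"))
        path = tmp_path_factory.mktemp("onto") / "t.csv"
        with path.open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerows(triples)
        onto = read_ontology(path)
        for pw, sc, cl in triples:
            assert onto.class_parent[cl] == sc
            assert onto.superclass_parent[sc] == pw
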