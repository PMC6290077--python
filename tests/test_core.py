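import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from resistex import (
    DatasetMeta,
    GeneSet,
    IntegratedTable,
    ProbeAnnotation,
    ProbeResult,
    ValidationError,
    derive_resistance_class,
    parse_filter,
    read_annotation,
    read_gene_sets,
    read_integrated_table,
    read_metadata,
    read_probe_results,
    subset_datasets,
    write_annotation,
    write_gene_sets,
    write_integrated_table,
    write_metadata,
    write_probe_results,
)
from resistex.errors import FilterError, SchemaError


class TestResistanceClass:
    @pytest.mark.parametrize(
        "mortality,expected",
        [
            (0, "high"),
            (20, "high"),
            (32.9, "high"),
            (33, "moderate"),
            (65.9, "moderate"),
            (66, "low"),
            (89.9, "low"),
            (90, "low"),
            (99.9, "low"),
            (100, "susceptible"),
        ],
    )
    def test_bins(self, mortality, expected):
        assert derive_resistance_class(mortality) == expected

    def test_partitions_the_full_mortality_range(self):
        # every value in [0, 100] maps to exactly one class
        for m in np.linspace(0, 100, 2001):
            assert derive_resistance_class(m) in {"high", "moderate", "low", "susceptible"}

    @pytest.mark.parametrize("bad", [-1, 100.1, float("nan")])
    def test_rejects_out_of_range(self, bad):
        with pytest.raises(ValidationError):
            derive_resistance_class(bad)


class TestDomainInvariants:
    def test_meta_rejects_inconsistent_class(self):
        with pytest.raises(ValidationError, match="inconsistent"):
            DatasetMeta(
                dataset_id="DSX", country="Kenya", species="gambiae",
                latitude=0.0, longitude=37.0, resistance_class="susceptible",
                mortality_pct=20.0, exposure="none", kdr_frequency=None,
                year=2012, comparator="Kisumu",
            )

    def test_meta_rejects_bad_coordinates(self):
        with pytest.raises(ValidationError, match="latitude"):
            DatasetMeta(
                dataset_id="DSX", country="Kenya", species="gambiae",
                latitude=95.0, longitude=37.0, resistance_class="high",
                exposure="none", year=2012, comparator="Kisumu",
            )

    def test_probe_result_bounds(self):
        with pytest.raises(ValidationError):
            ProbeResult("DS01", "P1", fold_change=-0.5, q_value=0.1)
        with pytest.raises(ValidationError):
            ProbeResult("DS01", "P1", fold_change=2.0, q_value=1.2)

    def test_annotation_cross_hyb_forced_for_multi_gene_probes(self):
        with pytest.raises(ValidationError, match="cross_hyb"):
            ProbeAnnotation("P1", ("AGAP000001-RA", "AGAP000002-RA"), cross_hyb=False)
        # splice variants of one gene do not force the flag
        ProbeAnnotation("P2", ("AGAP000001-RA", "AGAP000001-RB"), cross_hyb=False)

    def test_gene_set_must_be_nonempty(self):
        with pytest.raises(ValidationError):
            GeneSet("empty", frozenset())

    def test_table_missingness_must_agree(self):
        fc = pd.DataFrame({"DS01": [1.5, np.nan]}, index=["t1", "t2"])
        q = pd.DataFrame({"DS01": [0.01, 0.02]}, index=["t1", "t2"])
        with pytest.raises(ValidationError, match="missingness"):
            IntegratedTable(fc=fc, q=q)


class TestRoundTrips:
    def test_integrated_table(self, toy_table, tmp_path):
        path = tmp_path / "table.tsv"
        write_integrated_table(toy_table, path)
        back = read_integrated_table(path)
        assert back.equals(toy_table)
        assert back.fc.shape == (4, 3)

    def test_integrated_table_with_discordance(self, tmp_path):
        fc = pd.DataFrame({"DS01": [1.5, np.nan], "DS02": [2.0, 3.0]}, index=["t1", "t2"])
        q = pd.DataFrame({"DS01": [0.01, np.nan], "DS02": [0.02, 0.03]}, index=["t1", "t2"])
        disc = pd.DataFrame({"DS01": [False, True], "DS02": [False, False]}, index=["t1", "t2"])
        table = IntegratedTable(fc=fc, q=q, discordant=disc)
        path = tmp_path / "table.tsv"
        write_integrated_table(table, path)
        back = read_integrated_table(path)
        assert back.discordant.loc["t2", "DS01"]
        assert back.fc.equals(table.fc)

    def test_metadata(self, toy_meta, tmp_path):
        path = tmp_path / "meta.tsv"
        write_metadata(toy_meta, path)
        assert read_metadata(path) == toy_meta

    def test_annotation(self, tmp_path):
        ann = [
            ProbeAnnotation("P1", ("AGAP000001-RA",)),
            ProbeAnnotation("P2", ("AGAP000001-RA", "AGAP000002-RA"), cross_hyb=True),
        ]
        path = tmp_path / "ann.tsv"
        write_annotation(ann, path)
        assert read_annotation(path) == ann

    def test_gene_sets(self, tmp_path):
        sets = [GeneSet("detox", frozenset({"a", "b"})), GeneSet("tf", frozenset({"c"}))]
        path = tmp_path / "sets.tsv"
        write_gene_sets(sets, path)
        assert read_gene_sets(path) == sets

    def test_probe_results(self, tmp_path):
        res = [ProbeResult("DS01", "P1", 2.1, 0.01), ProbeResult("DS01", "P2", 0.5, 0.9)]
        path = tmp_path / "probes.tsv"
        write_probe_results(res, path)
        assert read_probe_results(path) == res


class TestTableReading:
    def test_bad_q_rejected_with_row_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "# resistex integrated-table v1\n"
            "transcript\tDS01_FC\tDS01_Q\n"
            "t1\t1.5\t0.01\n"
            "t2\t2.0\t1.2\n",
            encoding="utf-8",
        )
        with pytest.raises(ValidationError, match=r"rows \[4\]"):
            read_integrated_table(path)

    def test_negative_fc_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "# resistex integrated-table v1\n"
            "transcript\tDS01_FC\tDS01_Q\n"
            "t1\t-1.5\t0.01\n",
            encoding="utf-8",
        )
        with pytest.raises(ValidationError):
            read_integrated_table(path)

    def test_missing_fc_q_pairs_is_schema_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(
            "# resistex integrated-table v1\ntranscript\tvalue\nt1\t1.0\n", encoding="utf-8"
        )
        with pytest.raises(SchemaError):
            read_integrated_table(path)

    def test_annotation_drives_cross_hyb_flags(self, toy_table, tmp_path):
        path = tmp_path / "table.tsv"
        write_integrated_table(toy_table, path)
        ann = [ProbeAnnotation("P1", ("AGAP000001-RA", "AGAP000099-RA"), cross_hyb=True)]
        back = read_integrated_table(path, annotation=ann)
        assert bool(back.cross_hyb["AGAP000001-RA"])
        assert not bool(back.cross_hyb["AGAP000002-RA"])


class TestSubsetDatasets:
    def test_equality_filter(self, toy_meta):
        assert subset_datasets(toy_meta, {"species": "coluzzii"}) == ["DS01", "DS03"]

    def test_empty_filter_is_identity(self, toy_meta):
        assert subset_datasets(toy_meta) == ["DS01", "DS02", "DS03"]
        assert subset_datasets(toy_meta, {}) == ["DS01", "DS02", "DS03"]

    def test_unknown_field(self, toy_meta):
        with pytest.raises(FilterError):
            subset_datasets(toy_meta, {"flavour": "vanilla"})

    def test_callable_filter(self, toy_meta):
        got = subset_datasets(toy_meta, lambda m: m.exposure == "pyrethroid")
        assert got == ["DS01"]

    def test_conjunction_is_intersection(self, toy_meta):
        a = {"species": "coluzzii"}
        b = {"exposure": "DDT"}
        both = subset_datasets(toy_meta, {**a, **b})
        expected = [
            d for d in subset_datasets(toy_meta, a) if d in set(subset_datasets(toy_meta, b))
        ]
        assert both == expected

    def test_parse_filter(self):
        assert parse_filter("species=coluzzii, exposure=pyrethroid") == {
            "species": "coluzzii",
            "exposure": "pyrethroid",
        }
        with pytest.raises(FilterError):
            parse_filter("species coluzzii")


@settings(max_examples=50, derandomize=True, deadline=None)
@given(
    st.lists(
        st.tuples(
            st.sampled_from(["gambiae", "coluzzii", "arabiensis"]),
            st.sampled_from(["pyrethroid", "DDT", "none"]),
        ),
        min_size=0,
        max_size=8,
    )
)
def test_filter_conjunction_property(entries):
    """Filtering on two fields equals intersecting the single-field results."""
    meta = [
        DatasetMeta(
            dataset_id=f"D{i}", country="X", species=sp, latitude=0.0, longitude=0.0,
            resistance_class="high", exposure=ex, year=2010, comparator="ref",
        )
        for i, (sp, ex) in enumerate(entries)
    ]
    a = subset_datasets(meta, {"species": "coluzzii"})
    b = subset_datasets(meta, {"exposure": "pyrethroid"})
    both = subset_datasets(meta, {"species": "coluzzii", "exposure": "pyrethroid"})
    assert both == [d for d in a if d in set(b)]
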