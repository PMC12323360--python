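"""Lineage parsing, table harmonization, and cohort I/O."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from gutindices import (
    AbundanceProfile,
    CohortTable,
    apply_mgnify_fixes,
    parse_lineage,
    read_abundance_table,
    read_metadata_table,
    to_relative,
    write_cohort_table,
    write_metadata_table,
)
from gutindices.exceptions import (
    DegenerateSampleError,
    FormatError,
    MalformedLineageError,
    ValidationError,
)
from gutindices.profile_io import SampleMetadata


class TestParseLineage:
    def test_root_is_discarded_and_genus_extracted(self):
        lin = parse_lineage("Root;k__Bacteria;p__Proteobacteria;g__Escherichia", "mgnify")
        assert lin.genus == "Escherichia"
        assert lin.species is None
        assert lin.ranks[0] == ("k", "Bacteria")

    def test_epithet_joined_to_genus_as_binomial(self):
        lin = parse_lineage(
            "k__Bacteria|p__Firmicutes|f__Ruminococcaceae|g__Faecalibacterium|s__prausnitzii",
            "microbiomehd",
        )
        assert lin.genus == "Faecalibacterium"
        assert lin.species == "Faecalibacterium prausnitzii"

    def test_superkingdom_prefix_folds_into_kingdom(self):
        lin = parse_lineage("sk__Bacteria;g__Prevotella", "mgnify")
        assert lin.ranks[0] == ("k", "Bacteria")
        assert lin.genus == "Prevotella"

    @pytest.mark.parametrize("bad", ["", "   ", "Root;", "x__Wat", "k__Bacteria;k__Again"])
    def test_malformed_strings_raise(self, bad):
        with pytest.raises(MalformedLineageError):
            parse_lineage(bad, "plain")

    def test_rank_order_must_descend(self):
        with pytest.raises(MalformedLineageError):
            parse_lineage("g__Prevotella;k__Bacteria", "plain")

    def test_unassigned_genus_field_yields_no_genus(self):
        lin = parse_lineage("k__Bacteria;f__Lachnospiraceae;g__", "plain")
        assert lin.genus is None

    def test_bare_binomial_accepted_in_plain_dialect(self):
        lin = parse_lineage("Akkermansia muciniphila", "plain")
        assert lin.genus == "Akkermansia"
        assert lin.species == "Akkermansia muciniphila"

    def test_separator_equivalence_between_dialects(self):
        semi = "k__Bacteria;p__Firmicutes;g__Roseburia"
        pipe = semi.replace(";", "|")
        assert parse_lineage(semi, "mgnify") == parse_lineage(pipe, "microbiomehd")

    def test_spelled_round_trip(self):
        lin = parse_lineage("k__Bacteria|g__Faecalibacterium|s__prausnitzii", "microbiomehd")
        assert parse_lineage(lin.spelled(), "plain") == lin


class TestMgnifyFixes:
    RAW = [
        "SampleID\tERR1\tERR2",
        "sk__Bacteria;k__;p__Bacteroidetes;g__Prevotella\t5\t0",
        "Root;k__Bacteria;g__Prevotella\t1\t2",
    ]

    def test_all_four_edits(self):
        fixed = apply_mgnify_fixes(self.RAW)
        assert fixed[0] == "OTU ID\tERR1\tERR2"
        assert fixed[1].startswith("k__Bacteria|k__|p__Bacteroidetes|g__Prevotella\t")
        assert fixed[2].startswith("k__Bacteria|g__Prevotella\t")
        assert not any(";" in line or "Root" in line for line in fixed)

    def test_idempotent_on_its_own_output(self):
        once = apply_mgnify_fixes(self.RAW)
        assert apply_mgnify_fixes(once) == once

    def test_fixed_input_is_unchanged(self):
        clean = ["OTU ID\ta", "k__Bacteria|g__Dorea\t3"]
        assert apply_mgnify_fixes(clean) == clean

    def test_missing_header_raises(self):
        with pytest.raises(FormatError):
            apply_mgnify_fixes([])


class TestReadAbundanceTable:
    def _write(self, tmp_path, text, name="table.tsv"):
        path = tmp_path / name
        path.write_text(text)
        return path

    BASIC = (
        "taxon\ta\tb\n"
        "k__Bacteria;g__Escherichia\t10\t0\n"
        "k__Bacteria;g__Bacteroides\t5\t5\n"
        "k__Bacteria;g__Prevotella\t0\t10\n"
    )

    def test_profiles_and_totals(self, tmp_path):
        cohort = read_abundance_table(self._write(tmp_path, self.BASIC), "plain")
        assert cohort.sample_ids == ["a", "b"]
        assert cohort.profile("a").total() == 15
        assert cohort.profile("b").total() == 15

    def test_transposed_orientation_gives_identical_cohort(self, tmp_path):
        rows = [line.split("\t") for line in self.BASIC.strip().splitlines()]
        transposed = "\n".join("\t".join(col) for col in zip(*rows)) + "\n"
        a = read_abundance_table(self._write(tmp_path, self.BASIC, "t1.tsv"), "plain")
        b = read_abundance_table(
            self._write(tmp_path, transposed, "t2.tsv"), "plain", "samples_rows"
        )
        assert a == b

    def test_auto_orientation_detects_lineage_header(self, tmp_path):
        rows = [line.split("\t") for line in self.BASIC.strip().splitlines()]
        transposed = "\n".join("\t".join(col) for col in zip(*rows)) + "\n"
        b = read_abundance_table(
            self._write(tmp_path, transposed, "t3.tsv"), "plain", "auto"
        )
        assert b.sample_ids == ["a", "b"]

    def test_duplicate_lineage_rows_are_summed(self, tmp_path):
        text = (
            "taxon\ts\n"
            "k__Bacteria;g__Blautia\t20\n"
            "k__Bacteria;g__Blautia\t5\n"
        )
        cohort = read_abundance_table(self._write(tmp_path, text), "plain")
        # oracle: sum over duplicate keys
        assert cohort.profile("s").total() == 25
        assert len(cohort.profile("s").abundances) == 1

    def test_negative_abundance_reports_location(self, tmp_path):
        text = "taxon\ts\nk__Bacteria;g__Dorea\t-1\n"
        with pytest.raises(ValidationError, match="row 2"):
            read_abundance_table(self._write(tmp_path, text), "plain")

    def test_ragged_rows_raise_format_error(self, tmp_path):
        text = "taxon\ta\tb\nk__Bacteria;g__Dorea\t1\n"
        with pytest.raises(FormatError, match="ragged"):
            read_abundance_table(self._write(tmp_path, text), "plain")


class TestToRelative:
    def test_simple_arithmetic(self):
        from tests.conftest import genus_lineage

        a, b = genus_lineage("A"), genus_lineage("B")
        rel = to_relative(AbundanceProfile("s", {a: 10.0, b: 30.0}))
        assert rel.abundances == {a: 0.25, b: 0.75}

    def test_idempotent_and_zero_preserved(self):
        from tests.conftest import genus_lineage

        a, b, c = (genus_lineage(x) for x in "ABC")
        profile = AbundanceProfile("s", {a: 1.0, b: 0.0, c: 3.0})
        rel = to_relative(profile)
        assert rel.abundances[b] == 0.0
        again = to_relative(rel)
        assert all(
            math.isclose(again.abundances[k], rel.abundances[k], abs_tol=1e-12)
            for k in rel.abundances
        )
        assert math.isclose(sum(rel.abundances.values()), 1.0, abs_tol=1e-9)

    def test_all_zero_profile_raises(self):
        from tests.conftest import genus_lineage

        with pytest.raises(DegenerateSampleError):
            to_relative(AbundanceProfile("s", {genus_lineage("A"): 0.0}))


@given(
    values=st.lists(
        st.floats(min_value=0.0, max_value=1e6, allow_nan=False, width=64),
        min_size=2,
        max_size=6,
    )
)
def test_plain_dialect_round_trip_is_exact(tmp_path_factory, values):
    """Writing and re-reading the plain dialect reproduces abundances exactly."""
    from tests.conftest import genus_lineage

    genera = ["Escherichia", "Bacteroides", "Prevotella", "Dorea", "Blautia", "Roseburia"]
    abund = {genus_lineage(g): v for g, v in zip(genera, values)}
    if sum(abund.values()) == 0:
        abund[genus_lineage("Escherichia")] = 1.0
    cohort = CohortTable(profiles=[AbundanceProfile("s1", dict(abund))])
    path = tmp_path_factory.mktemp("roundtrip") / "t.tsv"
    write_cohort_table(cohort, path)
    back = read_abundance_table(path, "plain")
    expected = {k: v for k, v in abund.items() if v != 0.0}
    assert back.profile("s1").abundances == expected


def test_metadata_round_trip(tmp_path):
    meta = {
        "s1": SampleMetadata(age=30.0, gender="female", conditions=["IBS", "bloating"]),
        "s2": SampleMetadata(age=None, gender="unknown", conditions=[], phenotype="healthy"),
    }
    path = tmp_path / "meta.tsv"
    write_metadata_table(meta, path)
    assert read_metadata_table(path) == meta


def test_cohort_validate_reports_unmatched_entries(tiny_cohort, caplog):
    del tiny_cohort.metadata["s2"]
    tiny_cohort.metadata["ghost"] = SampleMetadata()
    with caplog.at_level("WARNING"):
        missing, orphans = tiny_cohort.validate()
    assert missing == ["s2"]
    assert orphans == ["ghost"]
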