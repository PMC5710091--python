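"""Candidate filtering, database flagging, and standard-format I/O."""

import io
import random

import pytest

from afquantile import (
    Approach,
    DatabaseSpec,
    DiseaseModel,
    VariantRecord,
    database_availability,
    filter_candidates,
    flag_database_variants,
    load_candidates,
    load_database,
)
from afquantile.filtering import FormatError, write_filter_report, write_flag_report

VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">
##INFO=<ID=AC,Number=A,Type=Integer,Description="Allele Count">
##INFO=<ID=AN,Number=1,Type=Integer,Description="Allele Number">
##contig=<ID=1>
##contig=<ID=2>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_vcf(path, body):
    path.write_text(VCF_HEADER + body)
    return path


class TestLoadDatabase:
    def test_fig1_tsv_has_five_records(self, fig1_paths, fig1_db):
        records = load_database(fig1_paths["database"], db=fig1_db)
        assert len(records) == 5
        causal = [r for r in records if r.id == "variant_4"]
        assert causal and causal[0].db_frequency == pytest.approx(0.02)
        assert causal[0].db_allele_count == 2

    def test_empty_database_file(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("chrom\tpos\tref\talt\tfrequency\n")
        assert load_database(path) == []

    def test_vcf_with_af(self, tmp_path):
        path = write_vcf(
            tmp_path / "db.vcf",
            "1\t100\trs1\tA\tG\t.\t.\tAF=0.02\n"
            "1\t200\t.\tC\tT\t.\t.\tAF=0.5\n",
        )
        records = load_database(path, db=DatabaseSpec(50))
        assert [r.db_frequency for r in records] == pytest.approx([0.02, 0.5])
        assert records[0].id == "rs1"

    def test_vcf_ac_an_takes_precedence_and_warns_on_mismatch(self, tmp_path):
        path = write_vcf(
            tmp_path / "db.vcf", "1\t100\t.\tA\tG\t.\t.\tAC=2;AN=90;AF=0.5\n"
        )
        with pytest.warns(UserWarning, match="AN=90"):
            records = load_database(path, db=DatabaseSpec(50))
        assert records[0].db_allele_count == 2
        assert records[0].db_frequency == pytest.approx(2 / 90)

    def test_multiallelic_site_decomposed(self, tmp_path):
        path = write_vcf(
            tmp_path / "db.vcf", "2\t300\t.\tG\tA,C\t.\t.\tAF=0.1,0.02\n"
        )
        records = load_database(path, db=DatabaseSpec(50))
        assert len(records) == 2
        assert {(r.chrom, r.pos, r.ref) for r in records} == {("2", 300, "G")}
        assert sorted(r.alt for r in records) == ["A", "C"]
        assert sorted(r.db_frequency for r in records) == pytest.approx([0.02, 0.1])

    def test_zero_frequency_records_dropped(self, tmp_path):
        path = write_vcf(
            tmp_path / "db.vcf",
            "1\t100\t.\tA\tG\t.\t.\tAF=0.0\n1\t200\t.\tC\tT\t.\t.\tAF=0.1\n",
        )
        records = load_database(path, db=DatabaseSpec(50))
        assert len(records) == 1 and records[0].pos == 200

    def test_missing_frequency_fields_is_format_error(self, tmp_path):
        path = write_vcf(tmp_path / "db.vcf", "1\t100\t.\tA\tG\t.\t.\t.\n")
        with pytest.raises(FormatError, match="1:100"):
            load_database(path, db=DatabaseSpec(50))

    def test_tsv_missing_columns_is_format_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("chrom\tpos\n1\t100\n")
        with pytest.raises(FormatError, match="missing required"):
            load_database(path)


class TestFilterCandidates:
    def test_toy_example_pattern(self, fig1_paths, fig1_model, fig1_db):
        """Quantile keeps the causal variant; absence and 1% remove it."""
        candidates = load_candidates(fig1_paths["candidates"])
        database = load_database(fig1_paths["database"], db=fig1_db)

        def retained_ids(approach):
            decisions = filter_candidates(
                candidates, database, approach, model=fig1_model, db=fig1_db
            )
            return {d.variant.id for d in decisions if d.retained}

        assert retained_ids("absence") == {"variant_6", "variant_7"}
        assert retained_ids("static") == {"variant_6", "variant_7"}
        assert retained_ids("quantile") == {"variant_4", "variant_6", "variant_7"}

    def test_candidate_absent_from_database_always_retained(self, fig1_model, fig1_db):
        lone = [VariantRecord("9", 999, "A", "T")]
        for approach in Approach:
            decisions = filter_candidates(
                lone, [], approach, model=fig1_model, db=fig1_db
            )
            assert decisions[0].retained and not decisions[0].in_database

    def test_common_variant_removed_under_all_approaches(self, fig1_model, fig1_db):
        v = VariantRecord("1", 100, "A", "G", db_frequency=0.5)
        for approach in Approach:
            decisions = filter_candidates(
                [v], [v], approach, model=fig1_model, db=fig1_db
            )
            assert not decisions[0].retained

    def test_exact_threshold_frequency_is_retained(self, fig1_model, fig1_db):
        """Removal demands f strictly above the threshold."""
        at_tv = VariantRecord("1", 100, "A", "G", db_frequency=0.03)
        decisions = filter_candidates(
            [at_tv], [at_tv], "quantile", model=fig1_model, db=fig1_db
        )
        assert decisions[0].retained
        just_above = VariantRecord("1", 100, "A", "G", db_allele_count=4)
        decisions = filter_candidates(
            [just_above], [just_above], "quantile", model=fig1_model, db=fig1_db
        )
        assert not decisions[0].retained

    def test_quantile_without_model_is_usage_error(self, fig1_db):
        with pytest.raises(ValueError, match="requires a disease model"):
            filter_candidates([], [], "quantile", db=fig1_db)

    def test_static_default_cutoff_follows_inheritance(self, fig1_db):
        v = VariantRecord("1", 100, "A", "G", db_frequency=0.005)
        ar = DiseaseModel(prevalence=1e-4, inheritance="AR")
        ad = DiseaseModel(prevalence=1e-4, inheritance="AD")
        # 0.005 <= 1% cutoff (AR) but > 0.1% cutoff (AD)
        assert filter_candidates([v], [v], "static", model=ar, db=fig1_db)[0].retained
        assert not filter_candidates([v], [v], "static", model=ad, db=fig1_db)[0].retained

    def test_nested_stringency_on_random_fixtures(self, fig1_model, fig1_db):
        """Absence removes at least whatever static/quantile remove."""
        rng = random.Random(42)
        for _ in range(20):
            candidates = [
                VariantRecord("1", pos, "A", "G") for pos in range(1, 31)
            ]
            database = [
                VariantRecord(
                    "1", pos, "A", "G",
                    db_allele_count=rng.choice([1, 2, 3, 5, 20, 80]),
                )
                for pos in rng.sample(range(1, 31), k=15)
            ]
            kept = {}
            for approach in Approach:
                decisions = filter_candidates(
                    candidates, database, approach, model=fig1_model, db=fig1_db
                )
                kept[approach] = {d.variant.key for d in decisions if d.retained}
            assert kept[Approach.ABSENCE] <= kept[Approach.STATIC]
            assert kept[Approach.ABSENCE] <= kept[Approach.QUANTILE]

    def test_deterministic_report(self, fig1_paths, fig1_model, fig1_db):
        candidates = load_candidates(fig1_paths["candidates"])
        database = load_database(fig1_paths["database"], db=fig1_db)

        def render():
            decisions = filter_candidates(
                candidates, database, "quantile", model=fig1_model, db=fig1_db
            )
            buf = io.StringIO()
            write_filter_report(decisions, buf, model=fig1_model, db=fig1_db)
            return buf.getvalue()

        assert render() == render()


class TestFlagDatabaseVariants:
    def test_toy_example_not_flagged(self, fig1_paths, fig1_model, fig1_db):
        """The causal variant at 2/100 is plausible under its own model."""
        database = load_database(fig1_paths["database"], db=fig1_db)
        report = flag_database_variants(database, fig1_model, fig1_db)
        causal = next(d for d in report.decisions if d.variant.id == "variant_4")
        assert causal.tail_probability == pytest.approx(0.2642, abs=5e-4)
        assert not causal.flagged
        assert report.n_tests == 5

    def test_zero_count_never_flagged(self, fig1_model, fig1_db):
        rec = VariantRecord("1", 100, "A", "G", db_allele_count=0)
        report = flag_database_variants([rec], fig1_model, fig1_db)
        assert report.decisions[0].tail_probability == 1.0
        assert not report.decisions[0].flagged

    def test_saturated_count_flagged(self, fig1_model, fig1_db):
        rec = VariantRecord("1", 100, "A", "G", db_allele_count=100)
        report = flag_database_variants([rec], fig1_model, fig1_db)
        assert report.decisions[0].tail_probability == pytest.approx(
            (1e-2) ** 100, abs=1e-150
        )
        assert report.decisions[0].flagged

    def test_flag_report_rendering(self, fig1_paths, fig1_model, fig1_db):
        database = load_database(fig1_paths["database"], db=fig1_db)
        report = flag_database_variants(database, fig1_model, fig1_db)
        buf = io.StringIO()
        write_flag_report(report, buf)
        text = buf.getvalue()
        assert "# n_tests: 5" in text
        assert text.count("\n") == 11 + 1 + 5  # summary + header + rows


class TestDatabaseAvailability:
    def test_zero_threshold_everything_available(self, fig1_paths, fig1_db):
        database = load_database(fig1_paths["database"], db=fig1_db)
        assert database_availability(database, 0.0, db=fig1_db) == 1.0

    def test_unit_threshold_nothing_available(self, fig1_paths, fig1_db):
        database = load_database(fig1_paths["database"], db=fig1_db)
        assert database_availability(database, 1.0, db=fig1_db) == 0.0

    def test_hand_enumerated_fraction(self, fig1_db):
        spectrum = [0.005, 0.02, 0.5, 0.009, 0.10]
        database = [
            VariantRecord("1", i + 1, "A", "G", db_frequency=f)
            for i, f in enumerate(spectrum)
        ]
        # strictly above 1%: 0.02, 0.5, 0.10
        assert database_availability(database, 0.01, db=fig1_db) == pytest.approx(3 / 5)

    def test_empty_database_is_an_error(self):
        with pytest.raises(ValueError, match="empty"):
            database_availability([], 0.01)

    def test_availability_grows_as_prevalence_drops(self, fig1_db):
        """Rarer diseases give lower thresholds, freeing more of the database."""
        from afquantile import allele_model, tv_threshold

        spectrum = [i / 200 for i in range(1, 100)]  # f = 0.005 .. 0.495
        database = [
            VariantRecord("1", i + 1, "A", "G", db_frequency=f)
            for i, f in enumerate(spectrum)
        ]
        fractions = []
        for pd in (1e-3, 1e-4, 1e-5, 1e-6):
            model = DiseaseModel(prevalence=pd, inheritance="AR", situation="b")
            tv = tv_threshold(allele_model(model).q_effective, fig1_db)
            fractions.append(database_availability(database, tv.tv_frequency, db=fig1_db))
        assert fractions == sorted(fractions)


class TestVariantRecord:
    def test_position_must_be_one_based(self):
        with pytest.raises(ValueError):
            VariantRecord("1", 0, "A", "G")

    def test_count_derived_from_frequency(self, fig1_db):
        rec = VariantRecord("1", 100, "A", "G", db_frequency=0.02)
        assert rec.count(fig1_db) == 2

    def test_matching_key(self):
        a = VariantRecord("1", 100, "A", "G")
        b = VariantRecord("1", 100, "A", "T")
        assert a.key != b.key
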