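"""Parsers: entry splitting, field extraction, round-trips against the ledger."""

import io

import pandas as pd
import pytest

from barcodeaudit import ingest
from barcodeaudit.clean import standardize_marker
from barcodeaudit.ingest import (
    BarcodeRecord,
    MalformedFileError,
    SchemaError,
    harmonize,
    parse_genbank_entry,
    read_bold,
    read_occurrences,
    split_entries,
)

MINIMAL_ENTRY = "LOCUS       TEST0001          10 bp    DNA     linear   INV 01-JAN-2020\n"


def _entry(body: str) -> str:
    return MINIMAL_ENTRY + body


class TestSplitEntries:
    def test_counts_terminated_entries(self):
        text = (_entry("") + "//\n") * 3
        assert len(split_entries(text)) == 3

    def test_empty_and_whitespace_input(self):
        assert split_entries("") == []
        assert split_entries("  \n\n") == []

    def test_unterminated_trailing_locus_names_offset(self):
        good = _entry("") + "//\n"
        text = good + MINIMAL_ENTRY
        with pytest.raises(MalformedFileError, match=str(len(good))):
            split_entries(text)

    def test_trailing_junk_without_locus_is_ignored(self):
        text = _entry("") + "//\nsome stray footer\n"
        assert len(split_entries(text)) == 1


class TestParseGenbankEntry:
    def test_requires_locus(self):
        with pytest.raises(ValueError, match="LOCUS"):
            parse_genbank_entry("DEFINITION  nothing\n")

    def test_minimal_entry_all_optional_absent(self):
        rec = parse_genbank_entry(MINIMAL_ENTRY)
        assert rec.record_id == "TEST0001"
        for field in (
            "species",
            "country",
            "latitude",
            "longitude",
            "locality_text",
            "collection_year",
            "submission_year",
            "publishing_institution",
            "sequence",
        ):
            assert getattr(rec, field) is None

    @pytest.mark.parametrize(
        "value,lat,lon",
        [
            ("14.50 N 121.00 E", 14.50, 121.00),
            ("14.50 S 121.00 W", -14.50, -121.00),
            ("9.7400 N 118.7300 E", 9.74, 118.73),
            ("not a coordinate", None, None),
            ("14.50 N", None, None),
            ("95.00 N 121.00 E", None, None),  # out of bounds
        ],
    )
    def test_lat_lon_parsing(self, value, lat, lon):
        rec = parse_genbank_entry(
            _entry(f'     source          1..10\n                     /lat_lon="{value}"\n')
        )
        assert rec.latitude == (pytest.approx(lat) if lat is not None else None)
        assert rec.longitude == (pytest.approx(lon) if lon is not None else None)

    @pytest.mark.parametrize(
        "value,year",
        [
            ("2014", 2014),
            ("Mar-2014", 2014),
            ("12-Mar-2014", 2014),
            ("2014-03-12", 2014),
            ("sometime in spring", None),
            ("32-Mar-2014", None),
            ("Mxx-2014", None),
        ],
    )
    def test_collection_date_forms(self, value, year):
        rec = parse_genbank_entry(
            _entry(
                f'     source          1..10\n                     /collection_date="{value}"\n'
            )
        )
        assert rec.collection_year == year

    def test_country_qualifier_splits_locality(self):
        rec = parse_genbank_entry(
            _entry(
                '     source          1..10\n'
                '                     /country="Philippines: Palawan, Puerto"\n'
            )
        )
        assert rec.country == "Philippines"
        assert rec.locality_text == "Palawan, Puerto"

    def test_submitted_journal_line(self):
        rec = parse_genbank_entry(
            _entry(
                "REFERENCE   1  (bases 1 to 10)\n"
                "  AUTHORS   Reyes,M.L.\n"
                "  TITLE     Direct Submission\n"
                "  JOURNAL   Submitted (05-MAR-2015) Ocean Genomics Lab, 12 Reef St\n"
            )
        )
        assert rec.submission_year == 2015
        assert rec.publishing_institution == "Ocean Genomics Lab"
        assert rec.publishing_author == "Reyes,M.L."

    def test_marker_precedence_gene_over_product_over_definition(self):
        body = (
            "DEFINITION  Conus magus maturase K gene.\n"
            "     CDS             <1..>10\n"
            '                     /product="cytochrome b"\n'
            "     gene            <1..>10\n"
            '                     /gene="COI"\n'
        )
        assert parse_genbank_entry(_entry(body)).marker_raw == "COI"
        body_no_gene = (
            "DEFINITION  Conus magus maturase K gene.\n"
            "     CDS             <1..>10\n"
            '                     /product="cytochrome b"\n'
        )
        assert parse_genbank_entry(_entry(body_no_gene)).marker_raw == "cytochrome b"
        body_def_only = "DEFINITION  Conus magus maturase K gene.\n"
        assert (
            parse_genbank_entry(_entry(body_def_only)).marker_raw
            == "Conus magus maturase K gene."
        )

    def test_sequence_strips_digits_and_spaces(self):
        rec = parse_genbank_entry(
            _entry("ORIGIN      \n        1 acgtacgtac gtac\n")
        )
        assert rec.sequence == "acgtacgtacgtac"


def test_parser_round_trip_against_ledger(small_corpus):
    """Undegraded fields of fixture entries parse back to their planted values."""
    led = small_corpus.ledger
    led = led[led["source_db"] == "genbank"].drop_duplicates("record_id")
    parsed = {
        r.record_id: r for r in ingest.parse_genbank(small_corpus.genbank_text)
    }
    assert set(parsed) == set(led["record_id"])
    for row in led.itertuples():
        rec = parsed[row.record_id]
        blanked = set(str(row.blanked_fields or "").split(";"))
        assert rec.species == row.species_label
        if "coordinates" not in blanked and pd.notna(row.latitude):
            assert rec.latitude == pytest.approx(row.latitude)
            assert rec.longitude == pytest.approx(row.longitude)
        if "country" not in blanked and pd.notna(row.country):
            assert rec.country == row.country
        if "locality_text" not in blanked and pd.notna(row.locality_text):
            assert rec.locality_text == row.locality_text
        if "collection_year" not in blanked:
            assert rec.collection_year == row.collection_year
        if "submission_year" not in blanked:
            assert rec.submission_year == row.submission_year
        if "institution" not in blanked:
            assert rec.publishing_institution == row.institution
        assert standardize_marker(rec.marker_raw) == row.marker


def test_parser_agrees_with_biopython(small_corpus):
    """Independent cross-check: Biopython reads the same flat file identically."""
    Bio_SeqIO = pytest.importorskip("Bio.SeqIO")
    ref = list(Bio_SeqIO.parse(io.StringIO(small_corpus.genbank_text), "genbank"))
    ours = ingest.parse_genbank(small_corpus.genbank_text)
    assert len(ref) == len(ours)
    for b, o in zip(ref, ours):
        assert b.name == o.record_id
        assert str(b.seq).lower() == o.sequence
        assert b.annotations["organism"] == o.species
        quals = b.features[0].qualifiers if b.features else {}
        if "country" in quals:
            country, _, locality = quals["country"][0].partition(":")
            assert o.country == country.strip()
            if locality.strip():
                assert o.locality_text == locality.strip()
        else:
            assert o.country is None


class TestReadBold:
    HEADER = "processid\tspecies_name\tcopyright_institutions\tlat\tlon\n"

    def test_header_only_yields_empty(self):
        assert read_bold(self.HEADER) == []

    def test_missing_processid_is_schema_error(self):
        with pytest.raises(SchemaError, match="processid"):
            read_bold("sampleid\tspecies_name\nX\tY\n")

    def test_copyright_country_lookup(self):
        table = self.HEADER + "P1\tConus magus\tX\t10.0\t120.0\n"
        (rec,) = read_bold(table, {"X": ("Philippines", None)})
        assert rec.copyright_country == "Philippines"
        assert rec.latitude == pytest.approx(10.0)

    def test_ledger_recovery(self, small_corpus):
        led = small_corpus.ledger
        led = led[led["source_db"] == "bold"].drop_duplicates("record_id")
        recs = {r.record_id: r for r in read_bold(small_corpus.bold)}
        assert set(recs) == set(led["record_id"])
        for row in led.itertuples():
            rec = recs[row.record_id]
            blanked = set(str(row.blanked_fields or "").split(";"))
            assert rec.species == row.species_label
            if "collection_year" not in blanked:
                assert rec.collection_year == row.collection_year
            if "institution" not in blanked and pd.notna(row.institution):
                assert rec.copyright_institution == row.institution


class TestReadOccurrences:
    HEADER = (
        "occurrenceID\tkingdom\tphylum\tclass\torder\tfamily\tgenus\tspecies\t"
        "decimalLatitude\tdecimalLongitude\tlocality\tstateProvince\t"
        "municipality\tcountry\n"
    )

    def test_missing_taxonomy_column_is_schema_error(self):
        with pytest.raises(SchemaError, match="family"):
            read_occurrences("occurrenceID\tkingdom\tphylum\tclass\torder\tspecies\n")

    def test_non_animal_plant_rows_dropped(self):
        rows = (
            "o1\tAnimalia\tChordata\tAves\tA\tB\tC\tC d\t10\t120\tloc\tP\tM\tPH\n"
            "o2\tFungi\tAscomycota\tX\tY\tZ\tW\tW v\t10\t120\tloc\tP\tM\tPH\n"
        )
        recs = read_occurrences(self.HEADER + rows)
        assert len(recs) == 1
        assert recs[0].kingdom == "animal"

    def test_ledger_recovery(self, small_corpus):
        led = small_corpus.ledger
        led = led[led["source_db"] == "occurrence"]
        recs = read_occurrences(small_corpus.occurrences)
        assert len(recs) == len(led)
        for rec, row in zip(recs, led.itertuples()):
            assert rec.species == row.species_true
            assert rec.province == row.province
            assert rec.kingdom == row.kingdom


class TestHarmonize:
    def test_concatenation_conservation(self):
        gb = [BarcodeRecord(record_id=f"G{i}", source_db="genbank") for i in range(3)]
        bd = [BarcodeRecord(record_id=f"B{i}", source_db="bold") for i in range(4)]
        assert len(harmonize(gb, bd)) == 7
        assert len(harmonize([], bd)) == 4

    def test_genbank_copyright_mirrors_publishing(self):
        gb = [
            BarcodeRecord(
                record_id="G1",
                source_db="genbank",
                publishing_institution="U",
                publishing_country="Utopia",
            )
        ]
        df = harmonize(gb, [])
        assert df.loc[0, "copyright_institution"] == "U"
        assert df.loc[0, "copyright_country"] == "Utopia"

    def test_fixture_corpus_row_count_matches_ledger(self, small_corpus):
        gb = ingest.parse_genbank(small_corpus.genbank_text)
        bd = read_bold(small_corpus.bold)
        df = harmonize(gb, bd)
        n_barcode = (
            small_corpus.ledger["source_db"].isin(["genbank", "bold"]).sum()
        )
        assert len(df) == n_barcode
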