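"""Marker standardization, locality resolution, taxonomy backfill, filters."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barcodeaudit import truth
from barcodeaudit._text import damerau_levenshtein, edit_threshold, normalize_name
from barcodeaudit.clean import (
    CANONICAL_MARKERS,
    MARKER_KEYWORDS,
    FilterLog,
    apply_filters,
    backfill_taxonomy,
    derive_taxonomy_table,
    flag_country_mismatch,
    mark_unidentified,
    resolve_locality,
    standardize_marker,
)
from barcodeaudit.gazetteer import Gazetteer, GazetteerEntry


class TestDamerauLevenshtein:
    @pytest.mark.parametrize(
        "a,b,d",
        [
            ("palawan", "palawan", 0),
            ("palawan", "plawan", 1),  # deletion
            ("palawan", "palwaan", 1),  # adjacent transposition
            ("palawan", "balawan", 1),  # substitution
            ("abc", "", 3),
            ("kitten", "sitting", 3),
        ],
    )
    def test_known_distances(self, a, b, d):
        assert damerau_levenshtein(a, b) == d

    @given(st.text(alphabet="abcd", max_size=8), st.text(alphabet="abcd", max_size=8))
    @settings(max_examples=200, derandomize=True)
    def test_symmetry_and_bounds(self, a, b):
        d = damerau_levenshtein(a, b)
        assert d == damerau_levenshtein(b, a)
        assert abs(len(a) - len(b)) <= d <= max(len(a), len(b))


class TestStandardizeMarker:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("cox1", "COI"),
            ("rubisco", "rbcL"),
            ("16S ribosomal RNA", "OTHER"),
            ("Conus magus cytochrome oxidase subunit I gene", "COI"),
            ("cyt-b", "CYTB"),
            ("MaturaseK", "matK"),
            ("internal transcribed spacer 2", "ITS2"),
            ("COI-5P", "COI"),
            (None, "OTHER"),
            ("", "OTHER"),
        ],
    )
    def test_examples(self, raw, expected):
        assert standardize_marker(raw) == expected

    @pytest.mark.parametrize(
        "marker,keyword",
        [(m, kw) for m, kws in MARKER_KEYWORDS.items() for kw in kws],
    )
    def test_every_search_keyword_maps_home(self, marker, keyword):
        assert standardize_marker(keyword) == marker

    @given(
        st.sampled_from(
            [kw for kws in MARKER_KEYWORDS.values() for kw in kws]
            + ["18S", "unknown marker", "COI", "CYTB", "rbcL", "matK", "ITS2"]
        )
    )
    @settings(derandomize=True)
    def test_idempotent_and_case_insensitive(self, raw):
        once = standardize_marker(raw)
        assert standardize_marker(once) == once
        assert standardize_marker(raw.upper()) == once
        assert standardize_marker(raw.lower()) == once


@pytest.fixture(scope="module")
def tiny_gaz():
    return Gazetteer(
        [
            GazetteerEntry("region", "Mimaropa", None),
            GazetteerEntry("region", "Calabarzon", None),
            GazetteerEntry(
                "province", "Palawan", "Mimaropa", ("Palawan Province",)
            ),
            GazetteerEntry("province", "Batangas", "Calabarzon", ()),
            GazetteerEntry("municipality", "Roxas", "Palawan", ()),
            GazetteerEntry("municipality", "Nasugbu", "Batangas", ()),
        ]
    )


class TestResolveLocality:
    def test_clean_chain(self, tiny_gaz):
        res = resolve_locality("Palawan, Roxas", None, tiny_gaz)
        assert res.as_tuple() == ("Palawan", "Roxas", None, "none")

    def test_municipality_alone_resolves_parent(self, tiny_gaz):
        res = resolve_locality("Roxas", None, tiny_gaz)
        assert res.as_tuple() == ("Palawan", "Roxas", None, "none")

    def test_variant_matches(self, tiny_gaz):
        res = resolve_locality("Palawan Province", None, tiny_gaz)
        assert (res.province, res.issue) == ("Palawan", "none")

    def test_misspelled_unique_near_match(self, tiny_gaz):
        res = resolve_locality("Plawan", None, tiny_gaz)
        assert (res.province, res.issue) == ("Palawan", "misspelled")

    def test_multiple_provinces(self, tiny_gaz):
        res = resolve_locality("Palawan and Batangas", None, tiny_gaz)
        assert res.as_tuple() == (None, None, None, "multiple")

    def test_mismatched_municipality(self, tiny_gaz):
        res = resolve_locality("Palawan, Nasugbu", None, tiny_gaz)
        assert res.issue == "mismatch"
        assert res.province is None

    def test_declared_province_mismatch(self, tiny_gaz):
        res = resolve_locality("Nasugbu", "Palawan", tiny_gaz)
        assert res.issue == "mismatch"

    def test_region_only_is_unspecified(self, tiny_gaz):
        res = resolve_locality("Mimaropa", None, tiny_gaz)
        assert res.as_tuple() == (None, None, None, "unspecified")

    def test_nothing_matches_is_unknown(self, tiny_gaz):
        res = resolve_locality("station 12", None, tiny_gaz)
        assert res.as_tuple() == (None, None, None, "unknown")

    def test_two_conditions_are_mixed(self, tiny_gaz):
        res = resolve_locality("Plawan, Batangas", None, tiny_gaz)
        assert res.issue == "mixed"

    def test_mixed_iff_two_base_conditions(self, tiny_gaz):
        """Issue is mixed exactly when >=2 independent base conditions hold,
        checked against a brute-force evaluation of each condition."""
        cases = [
            "Palawan, Roxas",
            "Plawan",
            "Palawan and Batangas",
            "Palawan, Nasugbu",
            "Plawan, Batangas",
            "Plawan, Nasugbu",
            "Mimaropa",
            "station 7",
        ]
        names = [
            (e.level, e.name, normalize_name(alias))
            for e in tiny_gaz.entries
            for alias in (e.name, *e.variants)
        ]
        for text in cases:
            tokens = [
                normalize_name(t)
                for t in text.replace(" and ", ",").split(",")
                if t.strip()
            ]
            exact = [
                (lvl, name)
                for tok in tokens
                for lvl, name, alias in names
                if tok == alias
            ]
            fuzzy_tokens = []
            for tok in tokens:
                if any(tok == alias for _, _, alias in names):
                    continue
                close = {
                    (lvl, name)
                    for lvl, name, alias in names
                    if damerau_levenshtein(tok, alias) <= edit_threshold(alias)
                }
                if len(close) == 1:
                    fuzzy_tokens.append(close.pop())
            provs = {n for lvl, n in exact + fuzzy_tokens if lvl == "province"}
            munis = {n for lvl, n in exact if lvl == "municipality"}
            conds = set()
            if fuzzy_tokens:
                conds.add("misspelled")
            if len(provs) >= 2:
                conds.add("multiple")
            if munis and provs:
                if any(
                    tiny_gaz.parent("municipality", m) not in provs
                    for m in munis
                ):
                    conds.add("mismatch")
            res = resolve_locality(text, None, tiny_gaz)
            if len(conds) >= 2:
                assert res.issue == "mixed", text
            elif len(conds) == 1:
                assert res.issue == next(iter(conds)), text


class TestCountryMismatch:
    def test_resolving_locality_is_not_flagged(self, tiny_gaz):
        assert not flag_country_mismatch(
            "Philippines", "Palawan, Roxas", tiny_gaz, {"Sabah"}
        )

    def test_foreign_place_flagged(self, tiny_gaz):
        assert flag_country_mismatch(
            "Philippines", "Sabah", tiny_gaz, {"Sabah"}
        )

    def test_other_country_not_flagged(self, tiny_gaz):
        assert not flag_country_mismatch(
            "Malaysia", "Sabah", tiny_gaz, {"Sabah"}
        )

    def test_fixture_decoys_all_flagged(self, small_corpus, small_reports):
        led = small_corpus.ledger
        n_mismatch_decoys = int(
            (led["decoy_kind"] == "foreign_mismatch").sum()
        )
        # every mismatch decoy was removed by the foreign rule
        log = small_reports["include_na_country"].filter_log
        removed_foreign = dict(log.rules)["foreign_sample"]
        n_country_decoys = int(
            (led["decoy_kind"] == "foreign_country").sum()
        )
        assert removed_foreign <= n_mismatch_decoys + n_country_decoys


@pytest.mark.parametrize(
    "species,expected",
    [
        ("Conus sp.", None),
        ("Conus magus", "Conus magus"),
        ("Gen. nov. sp. nov.", None),
        ("Epinephelus sp. A", None),
        ("Spondias", "Spondias"),  # 'sp' substring without the token
        (None, None),
    ],
)
def test_mark_unidentified(species, expected):
    assert mark_unidentified(species) == expected


def _occ_frame(rows):
    return pd.DataFrame(
        rows,
        columns=[
            "species", "kingdom", "phylum_division", "class", "order",
            "family", "genus",
        ],
    )


class TestTaxonomyTable:
    def test_unique_species_one_entry(self):
        rows = [("Conus magus", "animal", "Mollusca", "Gastropoda",
                 "Neogastropoda", "Conidae", "Conus")] * 2
        table = derive_taxonomy_table(_occ_frame(rows))
        assert len(table) == 1
        assert table.table["Conus magus"]["family"] == "Conidae"

    def test_conflicting_family_dropped_and_logged(self):
        rows = [
            ("Conus magus", "animal", "Mollusca", "Gastropoda",
             "Neogastropoda", "Conidae", "Conus"),
            ("Conus magus", "animal", "Mollusca", "Gastropoda",
             "Neogastropoda", "WrongFam", "Conus"),
        ]
        table = derive_taxonomy_table(_occ_frame(rows))
        assert len(table) == 0
        assert table.conflicts == ["Conus magus"]

    def test_fixture_table_matches_pool_species(self, small_corpus):
        from barcodeaudit.ingest import occurrences_to_frame, read_occurrences

        occ = occurrences_to_frame(read_occurrences(small_corpus.occurrences))
        table = derive_taxonomy_table(occ)
        led_occ = truth.occurrence_rows(small_corpus.ledger)
        assert set(table.table) == set(led_occ["species_true"]) | {
            "Homo sapiens"
        } & set(occ["species"])


def _barcode_frame(rows):
    cols = [
        "record_id", "marker", "country", "species", "kingdom",
        "phylum_division", "class", "order", "family", "genus",
    ]
    return pd.DataFrame(rows, columns=cols)


class TestBackfill:
    TABLE_ROWS = [
        ("Conus magus", "animal", "Mollusca", "Gastropoda",
         "Neogastropoda", "Conidae", "Conus"),
    ]

    def test_fills_absent_ranks_only(self):
        table = derive_taxonomy_table(_occ_frame(self.TABLE_ROWS))
        df = _barcode_frame(
            [("r1", "COI", "PH", "Conus magus", "animal",
              None, None, None, "KeptFamily", None)]
        )
        out, n_filled, n_incomplete = backfill_taxonomy(df, table)
        assert (n_filled, n_incomplete) == (1, 0)
        assert out.loc[0, "phylum_division"] == "Mollusca"
        assert out.loc[0, "family"] == "KeptFamily"  # never overwritten

    def test_species_not_in_table_counted_incomplete(self):
        table = derive_taxonomy_table(_occ_frame(self.TABLE_ROWS))
        df = _barcode_frame(
            [("r1", "COI", "PH", "Unknownus specius", "animal",
              None, None, None, None, None)]
        )
        out, n_filled, n_incomplete = backfill_taxonomy(df, table)
        assert (n_filled, n_incomplete) == (0, 1)
        assert out.loc[0, "phylum_division"] is None or pd.isna(
            out.loc[0, "phylum_division"]
        )

    def test_backfill_never_reduces_populated_ranks(self, small_reports):
        # indirectly: every analyzed record set retains complete key columns
        for rep in small_reports.values():
            assert rep.metadata["n_taxonomy_backfilled"] >= 0

    def test_ledger_predicts_still_incomplete(self, small_corpus):
        """Planted rank blanks on in-pool species are all recoverable."""
        from barcodeaudit.clean import (
            derive_taxonomy_table as dtt,
            mark_unidentified as mu,
        )
        from barcodeaudit.ingest import (
            harmonize,
            occurrences_to_frame,
            parse_genbank,
            read_bold,
            read_occurrences,
        )

        bar = harmonize(
            parse_genbank(small_corpus.genbank_text),
            read_bold(small_corpus.bold),
        )
        bar["species"] = bar["species"].map(mu)
        occ = occurrences_to_frame(read_occurrences(small_corpus.occurrences))
        table = dtt(occ)
        _, n_filled, n_incomplete = backfill_taxonomy(bar, table)
        led = truth.barcode_rows(small_corpus.ledger)
        occ_species = set(
            truth.occurrence_rows(small_corpus.ledger)["species_true"]
        )
        blanks = led["blanked_fields"].fillna("").map(
            lambda s: set(s.split(";"))
        )
        rank_blanked = blanks.map(
            lambda b: bool(b & {"phylum_division", "class", "order",
                                "family", "genus"})
        )
        identified = ~led["is_unidentified"].astype(bool)
        candidates = rank_blanked & identified
        expected_incomplete = int(
            (candidates & ~led["species_label"].isin(occ_species)).sum()
        )
        assert n_incomplete == expected_incomplete
        assert n_filled == int(candidates.sum()) - expected_incomplete


class TestApplyFilters:
    BASE = [
        ("A1", "COI", "Philippines", "Conus magus", "animal",
         "Mollusca", "Gastropoda", "Neogastropoda", "Conidae", "Conus"),
        ("A1", "COI", "Philippines", "Conus magus", "animal",
         "Mollusca", "Gastropoda", "Neogastropoda", "Conidae", "Conus"),
        ("A2", "OTHER", "Philippines", "Conus magus", "animal",
         "Mollusca", "Gastropoda", "Neogastropoda", "Conidae", "Conus"),
        ("A3", "COI", "Malaysia", "Conus magus", "animal",
         "Mollusca", "Gastropoda", "Neogastropoda", "Conidae", "Conus"),
        ("A4", "COI", None, "Conus magus", "animal",
         "Mollusca", "Gastropoda", "Neogastropoda", "Conidae", "Conus"),
        ("A5", "COI", "Philippines", "Homo sapiens", "animal",
         "Chordata", "Mammalia", "Primates", "Hominidae", "Homo"),
    ]

    def test_rule_order_and_counts(self):
        df = _barcode_frame(self.BASE)
        out, log = apply_filters(df, "include_na_country")
        assert dict(log.rules) == {
            "duplicate_id": 1,
            "marker_not_targeted": 1,
            "foreign_sample": 1,
            "homo_records": 1,
        }
        assert set(out["record_id"]) == {"A1", "A4"}
        log.check()

    def test_exclude_na_removes_absent_country(self):
        df = _barcode_frame(self.BASE)
        out, log = apply_filters(df, "exclude_na_country")
        assert dict(log.rules)["na_country"] == 1
        assert set(out["record_id"]) == {"A1"}

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            apply_filters(_barcode_frame(self.BASE), "banana")

    def test_conservation_invariant_violation_detected(self):
        log = FilterLog(input_count=5, rules=[("x", 1)], output_count=5)
        with pytest.raises(AssertionError):
            log.check()

    def test_mode_consistency_on_fixture(self, small_reports):
        inc = small_reports["include_na_country"]
        exc = small_reports["exclude_na_country"]
        assert exc.filter_log.output_count <= inc.filter_log.output_count
        inc.filter_log.check()
        exc.filter_log.check()

    def test_exclude_equals_include_minus_na_survivors(self, small_corpus, small_reports):
        led = small_corpus.ledger
        inc = truth.survivors(led, "include_na_country")
        exc = truth.survivors(led, "exclude_na_country")
        na_survivors = inc["blanked_fields"].fillna("").str.split(";").map(
            lambda b: "country" in b
        )
        assert len(exc) == len(inc) - int(na_survivors.sum())
        assert (
            small_reports["exclude_na_country"].filter_log.output_count
            == len(exc)
        )
        assert (
            small_reports["include_na_country"].filter_log.output_count
            == len(inc)
        )
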