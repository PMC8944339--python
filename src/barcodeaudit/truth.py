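"""Expected audit quantities derived from a TruthLedger by set algebra.

The fixture generator records every planted value, every degradation and
every decoy/duplicate flag in its ledger.  The functions here replay the
filter rules and tally definitions *directly on the ledger* -- independent
of the ingest/clean/analysis code paths -- so recovery tests can compare
pipeline output against ledger-derived expectations exactly.
"""

from __future__ import annotations

import pandas as pd

from .clean import CANONICAL_MARKERS, HOMO_SPECIES, RANK_COLUMNS

FOREIGN_DECOYS = ("foreign_country", "foreign_mismatch")
RESOLVING_ISSUES = ("none", "misspelled")  # issues that still yield a province


def _blank_sets(rows: pd.DataFrame) -> pd.Series:
    return rows["blanked_fields"].fillna("").map(
        lambda s: frozenset(p for p in str(s).split(";") if p)
    )


def barcode_rows(ledger: pd.DataFrame) -> pd.DataFrame:
    return ledger[ledger["source_db"].isin(["genbank", "bold"])].reset_index(
        drop=True
    )


def occurrence_rows(ledger: pd.DataFrame) -> pd.DataFrame:
    occ = ledger[ledger["source_db"] == "occurrence"]
    return occ[~occ["is_decoy"].astype(bool)].reset_index(drop=True)


def survivor_mask(rows: pd.DataFrame, mode: str) -> pd.Series:
    """Which barcode ledger rows survive the filter rules under a mode."""
    blanks = _blank_sets(rows)
    mask = ~rows["is_duplicate"].astype(bool)
    mask &= rows["marker"].isin(CANONICAL_MARKERS)
    mask &= ~rows["decoy_kind"].isin(FOREIGN_DECOYS)
    if mode == "exclude_na_country":
        mask &= ~blanks.map(lambda b: "country" in b)
    mask &= ~rows["species_label"].isin(HOMO_SPECIES)
    return mask


def survivors(ledger: pd.DataFrame, mode: str) -> pd.DataFrame:
    rows = barcode_rows(ledger)
    return rows[survivor_mask(rows, mode)].reset_index(drop=True)


def expected_filter_counts(ledger: pd.DataFrame, mode: str) -> dict[str, int]:
    """Per-rule removal counts, replaying the fixed filter order."""
    rows = barcode_rows(ledger)
    blanks = _blank_sets(rows)
    alive = pd.Series(True, index=rows.index)
    counts: dict[str, int] = {"input": len(rows)}

    dup = alive & rows["is_duplicate"].astype(bool)
    counts["duplicate_id"] = int(dup.sum())
    alive &= ~dup

    bad_marker = alive & ~rows["marker"].isin(CANONICAL_MARKERS)
    counts["marker_not_targeted"] = int(bad_marker.sum())
    alive &= ~bad_marker

    foreign = alive & rows["decoy_kind"].isin(FOREIGN_DECOYS)
    counts["foreign_sample"] = int(foreign.sum())
    alive &= ~foreign

    if mode == "exclude_na_country":
        na = alive & blanks.map(lambda b: "country" in b)
        counts["na_country"] = int(na.sum())
        alive &= ~na

    homo = alive & rows["species_label"].isin(HOMO_SPECIES)
    counts["homo_records"] = int(homo.sum())
    alive &= ~homo

    counts["output"] = int(alive.sum())
    return counts


def expected_missing_counts(ledger: pd.DataFrame, mode: str) -> dict[str, int]:
    """Missing-metadata counts over the surviving record set."""
    surv = survivors(ledger, mode)
    blanks = _blank_sets(surv)
    has = lambda f: blanks.map(lambda b: f in b)  # noqa: E731
    return {
        "total": len(surv),
        "collection_year": int(has("collection_year").sum()),
        "submission_year": int(has("submission_year").sum()),
        "copyright_institution": int(has("institution").sum()),
        "coordinates": int(has("coordinates").sum()),
        "any_location_metadata": int(
            (has("coordinates") & has("locality_text")).sum()
        ),
    }


def expected_issue_counts(ledger: pd.DataFrame, mode: str) -> dict[str, int]:
    """Planted issue-category counts among surviving locality-bearing records."""
    surv = survivors(ledger, mode)
    counts = surv["issue"].dropna().value_counts()
    return {k: int(v) for k, v in counts.items()}


def _has_effective_province(surv: pd.DataFrame) -> pd.Series:
    """A record contributes to province tallies when it kept its coordinates
    or its locality still resolves to a province."""
    blanks = _blank_sets(surv)
    has_coords = ~blanks.map(lambda b: "coordinates" in b)
    resolvable = surv["issue"].isin(RESOLVING_ISSUES)
    return has_coords | resolvable


def expected_province_counts(
    ledger: pd.DataFrame, mode: str
) -> dict[str, tuple[int, int]]:
    """(n_barcode, n_occurrence) per province, from planted provinces."""
    surv = survivors(ledger, mode)
    locatable = surv[_has_effective_province(surv)]
    bar = locatable["province"].value_counts()
    occ = occurrence_rows(ledger)["province"].value_counts()
    provinces = set(bar.index) | set(occ.index)
    return {
        p: (int(bar.get(p, 0)), int(occ.get(p, 0))) for p in provinces
    }


def expected_contributor_counts(
    ledger: pd.DataFrame, mode: str
) -> tuple[dict[str, int], int]:
    """(country -> count, n_unknown) over surviving records."""
    surv = survivors(ledger, mode)
    blanks = _blank_sets(surv)
    known = surv[~blanks.map(lambda b: "institution" in b)]
    counts = known["contributor_country"].value_counts()
    n_unknown = len(surv) - len(known)
    return {k: int(v) for k, v in counts.items()}, n_unknown


def _rank_present(surv: pd.DataFrame, rank: str, occ_species: set[str]) -> pd.Series:
    """Whether a rank value is present after the taxonomy backfill."""
    blanks = _blank_sets(surv)
    not_blanked = ~blanks.map(lambda b: rank in b)
    backfillable = ~surv["is_unidentified"].astype(bool) & surv[
        "species_label"
    ].isin(occ_species)
    return not_blanked | backfillable


def expected_taxon_counts(
    ledger: pd.DataFrame, mode: str, rank: str
) -> dict[tuple[str, str], tuple[int, int]]:
    """(kingdom, taxon) -> (n_barcode, n_occurrence) after backfill.

    Barcode records count when the rank is present post-backfill and the
    kingdom is recoverable (GenBank lineage always carries it; BOLD records
    recover it via the occurrence-derived species or phylum lookup).
    """
    if rank not in RANK_COLUMNS:
        raise ValueError(f"unknown rank {rank!r}")
    surv = survivors(ledger, mode)
    occ = occurrence_rows(ledger)
    occ_species = set(occ["species_true"].dropna())
    occ_phyla = set(occ["phylum_division"].dropna())
    blanks = _blank_sets(surv)

    present = _rank_present(surv, rank, occ_species)
    phylum_present = _rank_present(surv, "phylum_division", occ_species)
    species_known = ~surv["is_unidentified"].astype(bool) & surv[
        "species_label"
    ].isin(occ_species)
    kingdom_known = (
        (surv["source_db"] == "genbank")
        | species_known
        | (phylum_present & surv["phylum_division"].isin(occ_phyla))
    )
    counted = surv[present & kingdom_known]
    bar = counted.groupby(["kingdom", rank]).size()

    occ_counts = occ.groupby(["kingdom", rank]).size()
    keys = set(bar.index) | set(occ_counts.index)
    return {
        key: (int(bar.get(key, 0)), int(occ_counts.get(key, 0)))
        for key in keys
    }


def expected_trend_counts(
    ledger: pd.DataFrame, mode: str, axis: str
) -> dict[tuple[str, int], int]:
    """(contributor class, year) -> count over surviving records."""
    surv = survivors(ledger, mode)
    blanks = _blank_sets(surv)
    keep = ~blanks.map(lambda b: axis in b or "institution" in b)
    sub = surv[keep]
    cls = sub["contributor_country"].map(
        lambda c: "Philippines" if c == "Philippines" else "Foreign"
    )
    out: dict[tuple[str, int], int] = {}
    for (c, y), n in sub.groupby([cls, sub[axis].astype(int)]).size().items():
        out[(c, int(y))] = int(n)
    return out


def expected_region_matrix(
    ledger: pd.DataFrame, mode: str
) -> dict[tuple[str, str], int]:
    """(processing region, sampled region) -> count over surviving records."""
    surv = survivors(ledger, mode)
    blanks = _blank_sets(surv)
    inst_known = ~blanks.map(lambda b: "institution" in b)
    locatable = _has_effective_province(surv)
    sub = surv[
        inst_known & locatable & surv["contributor_region"].notna()
    ]
    out: dict[tuple[str, str], int] = {}
    grouped = sub.groupby(["contributor_region", "sampled_region"]).size()
    for key, n in grouped.items():
        out[(str(key[0]), str(key[1]))] = int(n)
    return out
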