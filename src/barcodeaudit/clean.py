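"""Standardization and filtering of harmonized barcode records.

Covers the cleaning steps applied between ingestion and analysis:

* gene-marker standardization onto the five actively searched barcode
  markers (COI, CYTB, rbcL, matK, ITS2) via the keyword sets used in the
  original database searches;
* resolution of free-text sampling localities against a hierarchical
  gazetteer, with a seven-way issue classification (none, misspelled,
  unspecified, unknown, multiple, mismatch, mixed);
* the "sp."/"gen." rule that voids placeholder species labels;
* a species-level taxonomy table derived from occurrence data, used to
  backfill missing higher ranks on barcode records;
* the record filters (deduplication, marker whitelist, foreign samples,
  Homo records) applied in a fixed order under the two country-NA modes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd

from ._text import normalize_name
from .gazetteer import Gazetteer

logger = logging.getLogger(__name__)

CANONICAL_MARKERS = ("COI", "CYTB", "rbcL", "matK", "ITS2")
OTHER_MARKER = "OTHER"

# Keyword sets mirror the database search terms for each marker.
MARKER_KEYWORDS: dict[str, tuple[str, ...]] = {
    "COI": (
        "COI",
        "co1",
        "cox1",
        "coxI",
        "cytochrome oxidase",
        "cytochrome c oxidase",
    ),
    "CYTB": ("cytb", "cyt-b", "cyt b", "cytochrome b", "cytochrome-b"),
    "rbcL": (
        "ribulose-1,5-bisphosphate carboxylase",
        "rbcl",
        "rubisco",
        "ribulose-bisphosphate carboxylase",
    ),
    "matK": ("matk", "MaturaseK", "maturase K"),
    "ITS2": ("internal transcribed spacer 2", "ITS2", "ITS"),
}

_MARKER_PATTERNS = {
    marker: [
        re.compile(r"(?<!\w)" + re.escape(kw.casefold()) + r"(?!\w)")
        for kw in kws
    ]
    for marker, kws in MARKER_KEYWORDS.items()
}

HOMO_SPECIES = frozenset({"Homo sapiens", "Homo luzonensis"})
RANK_COLUMNS = ("phylum_division", "class", "order", "family", "genus")


def standardize_marker(raw: str | None) -> str:
    """Map a raw gene-marker string to a canonical marker name.

    Matching is case-insensitive on whole keywords; the first marker (in
    COI, CYTB, rbcL, matK, ITS2 order) with a matching keyword wins; strings
    matching no keyword map to OTHER.  Idempotent on canonical values.
    """
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return OTHER_MARKER
    text = str(raw).casefold()
    for marker in CANONICAL_MARKERS:
        if any(p.search(text) for p in _MARKER_PATTERNS[marker]):
            return marker
    return OTHER_MARKER


# ---------------------------------------------------------------------------
# Locality resolution


@dataclass(frozen=True)
class LocalityResolution:
    province: str | None
    municipality: str | None
    barangay: str | None
    issue: str

    def as_tuple(self):
        return (self.province, self.municipality, self.barangay, self.issue)


ISSUE_CATEGORIES = (
    "none",
    "misspelled",
    "unspecified",
    "unknown",
    "multiple",
    "mismatch",
    "mixed",
)

_TOKEN_SPLIT = re.compile(r"[,;/]|\band\b|&", re.IGNORECASE)


def _tokenize(text: str) -> list[str]:
    return [
        t for t in (normalize_name(p) for p in _TOKEN_SPLIT.split(text)) if t
    ]


def resolve_locality(
    locality_text: str,
    declared_province: str | None,
    gazetteer: Gazetteer,
) -> LocalityResolution:
    """Resolve a free-text locality to administrative units with an issue tag.

    Base conditions (evaluated independently):

    * ``misspelled`` -- a token matches nothing exactly but lies within the
      edit-distance threshold of exactly one canonical/variant name;
    * ``multiple``   -- tokens name two or more distinct provinces;
    * ``mismatch``   -- a matched municipality (or barangay) whose gazetteer
      parent differs from every province named in the text or declared.

    Two or more distinct conditions give ``mixed``.  With no condition, a
    clean chain gives ``none``; a match only above province level gives
    ``unspecified``; no match at all gives ``unknown``.  Resolved units are
    reported only for the ``none`` and ``misspelled`` outcomes.
    """
    tokens = _tokenize(locality_text)
    matched: dict[str, set[str]] = {
        "region": set(),
        "province": set(),
        "municipality": set(),
        "barangay": set(),
    }
    fuzzy_hit = False
    any_match = False
    for tok in tokens:
        ref = gazetteer.lookup(tok)
        if ref is None:
            ref = gazetteer.fuzzy_lookup(tok)
            if ref is not None:
                fuzzy_hit = True
        if ref is not None:
            any_match = True
            matched[ref[0]].add(ref[1])

    declared: str | None = None
    if declared_province:
        ref = gazetteer.lookup(normalize_name(str(declared_province)))
        if ref is not None and ref[0] == "province":
            declared = ref[1]

    provinces = set(matched["province"])
    context = provinces | ({declared} if declared else set())
    muni_parents = {
        gazetteer.parent("municipality", m) for m in matched["municipality"]
    }

    conditions: set[str] = set()
    if fuzzy_hit:
        conditions.add("misspelled")
    if len(provinces) >= 2 or (not provinces and len(muni_parents) >= 2):
        conditions.add("multiple")
    if matched["municipality"] and context:
        if any(p not in context for p in muni_parents):
            conditions.add("mismatch")
    for b in matched["barangay"]:
        parent_muni = gazetteer.parent("barangay", b)
        if matched["municipality"] and parent_muni not in matched["municipality"]:
            conditions.add("mismatch")

    if not any_match:
        return LocalityResolution(None, None, None, "unknown")
    if len(conditions) >= 2:
        return LocalityResolution(None, None, None, "mixed")
    if len(conditions) == 1:
        issue = next(iter(conditions))
        if issue == "misspelled":
            prov, muni, brgy = _resolve_chain(matched, gazetteer)
            return LocalityResolution(prov, muni, brgy, "misspelled")
        return LocalityResolution(None, None, None, issue)
    # no base condition
    prov, muni, brgy = _resolve_chain(matched, gazetteer)
    if prov is None:
        return LocalityResolution(None, None, None, "unspecified")
    return LocalityResolution(prov, muni, brgy, "none")


def _resolve_chain(matched, gazetteer):
    """Pick the consistent province/municipality/barangay chain, if any."""
    province = next(iter(matched["province"]), None)
    municipality = next(iter(matched["municipality"]), None)
    barangay = next(iter(matched["barangay"]), None)
    if province is None and municipality is not None:
        province = gazetteer.parent("municipality", municipality)
    if municipality is None and barangay is not None:
        municipality = gazetteer.parent("barangay", barangay)
        if province is None and municipality is not None:
            province = gazetteer.parent("municipality", municipality)
    return province, municipality, barangay


def resolve_records(
    records: pd.DataFrame, gazetteer: Gazetteer
) -> pd.DataFrame:
    """Resolve locality text (or a declared province) for every record.

    Adds/overwrites the ``province``, ``municipality``, ``barangay`` and
    ``issue`` columns.  Records without locality text but with a declared
    province column resolve that name directly (no issue is assigned, since
    the issue classification applies to descriptive locality text only).
    """
    out = records.copy()
    provinces = []
    municipalities = []
    barangays = []
    issues = []
    has_declared = "declared_province" in out.columns
    for row in out.itertuples(index=False):
        text = getattr(row, "locality_text", None)
        declared = getattr(row, "declared_province", None) if has_declared else None
        if isinstance(text, str) and text.strip():
            res = resolve_locality(text, declared, gazetteer)
            provinces.append(res.province)
            municipalities.append(res.municipality)
            barangays.append(res.barangay)
            issues.append(res.issue)
        elif isinstance(declared, str) and declared.strip():
            ref = gazetteer.lookup(normalize_name(declared))
            prov = ref[1] if ref is not None and ref[0] == "province" else None
            provinces.append(prov)
            municipalities.append(None)
            barangays.append(None)
            issues.append(None)
        else:
            provinces.append(None)
            municipalities.append(None)
            barangays.append(None)
            issues.append(None)
    out["province"] = provinces
    out["municipality"] = municipalities
    out["barangay"] = barangays
    out["issue"] = issues
    return out


def flag_country_mismatch(
    country: str | None,
    locality_text: str | None,
    gazetteer: Gazetteer,
    foreign_places: set[str],
) -> bool:
    """True when a record claims Philippines but its locality is foreign.

    The locality must resolve to nothing in the gazetteer at every level
    while naming a place on the supplied foreign-place list; such records
    are relabelled foreign before filtering.
    """
    if not country or normalize_name(str(country)) != "philippines":
        return False
    if not locality_text or not str(locality_text).strip():
        return False
    res = resolve_locality(str(locality_text), None, gazetteer)
    if res.issue != "unknown":
        return False
    foreign_norm = {normalize_name(p) for p in foreign_places}
    return any(tok in foreign_norm for tok in _tokenize(str(locality_text)))


def flag_country_mismatches(
    records: pd.DataFrame, gazetteer: Gazetteer, foreign_places
) -> pd.DataFrame:
    out = records.copy()
    out["foreign_mismatch"] = [
        flag_country_mismatch(
            getattr(row, "country", None),
            getattr(row, "locality_text", None),
            gazetteer,
            set(foreign_places),
        )
        for row in out.itertuples(index=False)
    ]
    return out


# ---------------------------------------------------------------------------
# Taxonomy

_UNIDENTIFIED = re.compile(r"(?:^|[\s(])(?:sp|gen)\.(?=$|[\s).,])", re.IGNORECASE)


def mark_unidentified(species: str | None) -> str | None:
    """Void placeholder species labels containing the tokens "sp." or "gen."."""
    if species is None or (isinstance(species, float) and pd.isna(species)):
        return None
    if _UNIDENTIFIED.search(str(species)):
        return None
    return species


@dataclass
class TaxonomyTable:
    """Species -> higher-rank lookup derived from unique occurrence species."""

    table: dict[str, dict[str, str]] = field(default_factory=dict)
    phylum_kingdom: dict[str, str] = field(default_factory=dict)
    conflicts: list[str] = field(default_factory=list)

    def __contains__(self, species: str) -> bool:
        return species in self.table

    def __len__(self) -> int:
        return len(self.table)


def derive_taxonomy_table(occurrences: pd.DataFrame) -> TaxonomyTable:
    """Build the species-level taxonomy table from occurrence records.

    Only rows with a species name and all five higher ranks contribute.
    Species whose rows disagree on any higher rank are dropped and logged,
    keeping the table deterministic.
    """
    cols = ["species", "kingdom", *RANK_COLUMNS]
    sub = occurrences[cols].dropna(subset=["species", *RANK_COLUMNS])
    table: dict[str, dict[str, str]] = {}
    conflicts: list[str] = []
    grouped = sub.drop_duplicates().groupby("species", sort=True)
    for species, grp in grouped:
        if len(grp) > 1:
            conflicts.append(str(species))
            continue
        row = grp.iloc[0]
        table[str(species)] = {
            "kingdom": row["kingdom"],
            **{r: row[r] for r in RANK_COLUMNS},
        }
    if conflicts:
        logger.warning(
            "dropped %d species with conflicting higher ranks", len(conflicts)
        )
    phylum_kingdom: dict[str, str] = {}
    pk = sub[["phylum_division", "kingdom"]].dropna().drop_duplicates()
    for phylum, grp in pk.groupby("phylum_division"):
        if grp["kingdom"].nunique() == 1:
            phylum_kingdom[str(phylum)] = grp["kingdom"].iloc[0]
    return TaxonomyTable(table, phylum_kingdom, conflicts)


def backfill_taxonomy(
    records: pd.DataFrame, table: TaxonomyTable
) -> tuple[pd.DataFrame, int, int]:
    """Fill missing higher ranks from the occurrence-derived table.

    Records with a species name but one or more absent higher ranks receive
    every absent rank from the table when the species is present; present
    values are never overwritten.  Missing kingdoms are additionally filled
    from the species entry or, failing that, the phylum->kingdom map.
    Returns (records, n_filled, n_still_incomplete) where the counts refer
    to species-identified records with incomplete higher ranks before the
    fill.
    """
    out = records.copy()
    candidates = 0
    still_incomplete = 0
    for idx, row in out.iterrows():
        species = row.get("species")
        if species is None or pd.isna(species):
            continue
        missing = [r for r in RANK_COLUMNS if pd.isna(row.get(r))]
        if missing:
            candidates += 1
            entry = table.table.get(str(species))
            if entry is not None:
                for r in missing:
                    out.at[idx, r] = entry[r]
                missing = []
            if missing:
                still_incomplete += 1
        if "kingdom" in out.columns and pd.isna(out.at[idx, "kingdom"]):
            entry = table.table.get(str(species))
            if entry is not None:
                out.at[idx, "kingdom"] = entry["kingdom"]
    # kingdom via phylum for records the species lookup could not cover
    if "kingdom" in out.columns:
        mask = out["kingdom"].isna() & out["phylum_division"].notna()
        out.loc[mask, "kingdom"] = out.loc[mask, "phylum_division"].map(
            table.phylum_kingdom
        )
    return out, candidates - still_incomplete, still_incomplete


# ---------------------------------------------------------------------------
# Filters


@dataclass
class FilterLog:
    """Ordered per-rule removal counts with a conservation invariant."""

    input_count: int
    rules: list[tuple[str, int]] = field(default_factory=list)
    output_count: int = 0
    notes: dict[str, int] = field(default_factory=dict)

    def check(self) -> None:
        removed = sum(n for _, n in self.rules)
        if self.input_count != self.output_count + removed:
            raise AssertionError(
                f"filter log not conserved: {self.input_count} != "
                f"{self.output_count} + {removed}"
            )

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.input_count)]
        rows += [(f"removed:{name}", n) for name, n in self.rules]
        rows.append(("output", self.output_count))
        rows += [(f"note:{k}", v) for k, v in self.notes.items()]
        return pd.DataFrame(rows, columns=["rule", "count"])


FILTER_MODES = ("include_na_country", "exclude_na_country")


def apply_filters(
    records: pd.DataFrame, mode: str
) -> tuple[pd.DataFrame, FilterLog]:
    """Apply the record filters in fixed order under a country-NA mode.

    Order: (1) deduplicate on record id keeping the first occurrence,
    (2) keep only the five actively searched markers, (3) drop foreign
    records (explicit foreign country or mismatch-flagged; absent country
    is kept in include_na mode and dropped in exclude_na mode), (4) drop
    Homo sapiens / Homo luzonensis.
    """
    if mode not in FILTER_MODES:
        raise ValueError(f"unknown mode {mode!r}")
    log = FilterLog(input_count=len(records))
    df = records

    has_id = df["record_id"].notna()
    dup = df["record_id"].duplicated(keep="first") & has_id
    log.rules.append(("duplicate_id", int(dup.sum())))
    log.notes["records_without_id"] = int((~has_id).sum())
    df = df[~dup]

    bad_marker = ~df["marker"].isin(CANONICAL_MARKERS)
    log.rules.append(("marker_not_targeted", int(bad_marker.sum())))
    df = df[~bad_marker]

    country_norm = df["country"].map(
        lambda c: normalize_name(str(c)) if pd.notna(c) else None
    )
    foreign = country_norm.notna() & (country_norm != "philippines")
    if "foreign_mismatch" in df.columns:
        foreign |= df["foreign_mismatch"].fillna(False).astype(bool)
    log.rules.append(("foreign_sample", int(foreign.sum())))
    df = df[~foreign]

    if mode == "exclude_na_country":
        na_country = df["country"].isna()
        log.rules.append(("na_country", int(na_country.sum())))
        df = df[~na_country]

    homo = df["species"].isin(HOMO_SPECIES)
    log.rules.append(("homo_records", int(homo.sum())))
    df = df[~homo]

    log.output_count = len(df)
    log.check()
    return df.reset_index(drop=True), log


def filter_occurrences(
    occurrences: pd.DataFrame,
) -> tuple[pd.DataFrame, int]:
    """Drop Homo sapiens / Homo luzonensis occurrence rows."""
    homo = occurrences["species"].isin(HOMO_SPECIES)
    return occurrences[~homo].reset_index(drop=True), int(homo.sum())
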