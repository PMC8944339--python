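"""Parsers turning raw record sources into harmonized barcode/occurrence tables.

Three sources are supported: GenBank flat-file text (one or more entries
terminated by ``//``), a BOLD-style tab-delimited export, and a Darwin-Core
style occurrence table.  GenBank extraction follows the seven-field scheme
used for barcode-record audits: (1) organism name and lineage, (2) publishing
author, (3) publishing institution, (4) submission year, (5) source
qualifiers (country, coordinates, locality, collection date), (6) raw gene
marker, (7) nucleotide sequence.  Absent blocks yield absent fields, never
failures.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import asdict, dataclass, fields as dc_fields

import pandas as pd

logger = logging.getLogger(__name__)


class MalformedFileError(ValueError):
    """Raised when flat-file text has an unterminated trailing entry."""


class SchemaError(ValueError):
    """Raised when a tabular source lacks a mandatory column."""


@dataclass
class BarcodeRecord:
    """One harmonized DNA-barcode entry from GenBank or BOLD."""

    record_id: str | None = None
    source_db: str | None = None  # genbank | bold
    marker_raw: str | None = None
    marker: str | None = None
    sequence: str | None = None
    kingdom: str | None = None  # animal | plant
    phylum_division: str | None = None
    class_: str | None = None
    order: str | None = None
    family: str | None = None
    genus: str | None = None
    species: str | None = None
    country: str | None = None
    latitude: float | None = None
    longitude: float | None = None
    locality_text: str | None = None
    declared_province: str | None = None
    province: str | None = None
    municipality: str | None = None
    barangay: str | None = None
    issue: str | None = None
    collection_year: int | None = None
    submission_year: int | None = None
    publishing_author: str | None = None
    publishing_institution: str | None = None
    publishing_country: str | None = None
    copyright_institution: str | None = None
    copyright_country: str | None = None
    storing_institution: str | None = None
    storing_country: str | None = None
    specimen_voucher: str | None = None
    processing_region: str | None = None
    sampled_region: str | None = None


@dataclass
class OccurrenceRecord:
    """One species-occurrence row (Darwin-Core style)."""

    occurrence_id: str | None = None
    kingdom: str | None = None
    phylum_division: str | None = None
    class_: str | None = None
    order: str | None = None
    family: str | None = None
    genus: str | None = None
    species: str | None = None
    latitude: float | None = None
    longitude: float | None = None
    locality_text: str | None = None
    province: str | None = None
    municipality: str | None = None
    barangay: str | None = None
    country: str | None = None


def _columns(cls) -> list[str]:
    return [
        "class" if f.name == "class_" else f.name for f in dc_fields(cls)
    ]


BARCODE_COLUMNS = _columns(BarcodeRecord)
OCCURRENCE_COLUMNS = _columns(OccurrenceRecord)


def _to_frame(records, cls, columns) -> pd.DataFrame:
    rows = []
    for r in records:
        d = asdict(r)
        d["class"] = d.pop("class_")
        rows.append(d)
    df = pd.DataFrame(rows, columns=columns)
    for col in ("latitude", "longitude"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("collection_year", "submission_year"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    return df


def records_to_frame(records: list[BarcodeRecord]) -> pd.DataFrame:
    return _to_frame(records, BarcodeRecord, BARCODE_COLUMNS)


def occurrences_to_frame(records: list[OccurrenceRecord]) -> pd.DataFrame:
    return _to_frame(records, OccurrenceRecord, OCCURRENCE_COLUMNS)


# ---------------------------------------------------------------------------
# GenBank flat files


def split_entries(flatfile_text: str) -> list[str]:
    """Split concatenated GenBank flat-file text on ``//`` terminator lines."""
    entries: list[str] = []
    current: list[str] = []
    offset = 0
    current_start = 0
    for line in flatfile_text.splitlines(keepends=True):
        if line.strip() == "//":
            entries.append("".join(current))
            current = []
            current_start = offset + len(line)
        else:
            if not current:
                current_start = offset
            current.append(line)
        offset += len(line)
    trailing = "".join(current)
    if re.search(r"^LOCUS", trailing, re.MULTILINE):
        raise MalformedFileError(
            "unterminated entry with LOCUS line starting at byte "
            f"{current_start}"
        )
    return entries


_QUALIFIER = re.compile(r'/(\w+)="([^"]*)"', re.DOTALL)
_MONTHS = {
    m: i + 1
    for i, m in enumerate(
        "jan feb mar apr may jun jul aug sep oct nov dec".split()
    )
}


def _collection_year(value: str) -> int | None:
    """Reduce a collection date to its year.

    Accepted forms: ``YYYY``, ``Mon-YYYY``, ``DD-Mon-YYYY`` and ISO
    ``YYYY-MM-DD``; anything else yields None with a logged warning.
    """
    v = value.strip()
    m = re.fullmatch(r"(\d{4})", v)
    if m:
        return int(m.group(1))
    m = re.fullmatch(r"([A-Za-z]{3})-(\d{4})", v)
    if m and m.group(1).lower() in _MONTHS:
        return int(m.group(2))
    m = re.fullmatch(r"(\d{1,2})-([A-Za-z]{3})-(\d{4})", v)
    if m and m.group(2).lower() in _MONTHS and 1 <= int(m.group(1)) <= 31:
        return int(m.group(3))
    m = re.fullmatch(r"(\d{4})-(\d{2})(?:-(\d{2}))?", v)
    if m:
        return int(m.group(1))
    logger.warning("unparseable collection date %r", value)
    return None


def _lat_lon(value: str) -> tuple[float | None, float | None]:
    """Parse a ``/lat_lon`` string; N/E positive, S/W negative.

    Malformed strings leave both coordinates absent so that downstream
    missingness counts stay coherent.
    """
    m = re.fullmatch(
        r"\s*(\d+(?:\.\d+)?)\s*([NS])[ ,]+(\d+(?:\.\d+)?)\s*([EW])\s*",
        value,
    )
    if not m:
        return None, None
    lat = float(m.group(1)) * (1 if m.group(2) == "N" else -1)
    lon = float(m.group(3)) * (1 if m.group(4) == "E" else -1)
    if not (-90 <= lat <= 90 and -180 <= lon <= 180):
        return None, None
    return lat, lon


def _first(pattern: str, text: str, flags=re.MULTILINE) -> str | None:
    m = re.search(pattern, text, flags)
    return m.group(1).strip() if m else None


def parse_genbank_entry(entry_text: str) -> BarcodeRecord:
    """Extract barcode-relevant fields from one GenBank entry.

    Requires a LOCUS line; every other block is optional and yields absent
    fields when missing.
    """
    locus = _first(r"^LOCUS\s+(\S+)", entry_text)
    if locus is None:
        raise ValueError("entry has no LOCUS line")
    rec = BarcodeRecord(source_db="genbank")
    rec.record_id = _first(r"^ACCESSION\s+(\S+)", entry_text) or locus

    definition = _first(
        r"^DEFINITION\s+(.+?)(?=^\S|\Z)", entry_text, re.MULTILINE | re.DOTALL
    )
    if definition:
        definition = re.sub(r"\s+", " ", definition).strip()

    organism = _first(r"^ {2}ORGANISM\s+(.+)$", entry_text)
    lineage_block = _first(
        r"^ {2}ORGANISM\s+.+\n((?: {6,}.+\n?)+)",
        entry_text,
        re.MULTILINE,
    )
    lineage: list[str] = []
    if lineage_block:
        joined = re.sub(r"\s+", " ", lineage_block).strip().rstrip(".")
        lineage = [p.strip() for p in joined.split(";") if p.strip()]
    rec.species = organism
    if "Metazoa" in lineage:
        rec.kingdom = "animal"
        marker_idx = lineage.index("Metazoa")
    elif "Viridiplantae" in lineage:
        rec.kingdom = "plant"
        marker_idx = lineage.index("Viridiplantae")
    else:
        marker_idx = None
    if marker_idx is not None:
        ranks = lineage[marker_idx + 1 :]
        if len(ranks) == 5:
            (
                rec.phylum_division,
                rec.class_,
                rec.order,
                rec.family,
                rec.genus,
            ) = ranks

    rec.publishing_author = _first(r"^ {2}AUTHORS\s+(.+)$", entry_text)
    journal = _first(
        r"^ {2}JOURNAL\s+(.+?)(?=^ {0,2}\S|\Z)",
        entry_text,
        re.MULTILINE | re.DOTALL,
    )
    if journal:
        journal = re.sub(r"\s+", " ", journal).strip()
        m = re.search(r"Submitted\s+\((\d{2})-([A-Za-z]{3})-(\d{4})\)\s*(.*)", journal)
        if m:
            rec.submission_year = int(m.group(3))
            rest = m.group(4).strip()
            if rest:
                rec.publishing_institution = rest.split(",")[0].strip()
        elif journal.casefold() != "unpublished":
            # direct-submission entry lacking a dated Submitted line: the
            # journal text itself names the institution
            rec.publishing_institution = journal.split(",")[0].strip() or None

    quals = dict(
        (k, re.sub(r"\s+", " ", v).strip())
        for k, v in _QUALIFIER.findall(entry_text)
    )
    if "country" in quals:
        parts = quals["country"].split(":", 1)
        rec.country = parts[0].strip() or None
        if len(parts) == 2 and parts[1].strip():
            rec.locality_text = parts[1].strip()
    if "lat_lon" in quals:
        rec.latitude, rec.longitude = _lat_lon(quals["lat_lon"])
    if "collection_date" in quals:
        rec.collection_year = _collection_year(quals["collection_date"])
    rec.specimen_voucher = quals.get("specimen_voucher")
    if quals.get("organism"):
        rec.species = quals["organism"]

    # marker precedence: gene qualifier > product qualifier > DEFINITION
    rec.marker_raw = quals.get("gene") or quals.get("product") or definition

    origin = re.search(r"^ORIGIN.*?$([\s\S]*)", entry_text, re.MULTILINE)
    if origin:
        seq = re.sub(r"[\d\s/]+", "", origin.group(1))
        rec.sequence = seq or None
    return rec


def parse_genbank(flatfile_text: str) -> list[BarcodeRecord]:
    """Split and parse a whole flat file."""
    return [parse_genbank_entry(e) for e in split_entries(flatfile_text)]


# ---------------------------------------------------------------------------
# Tabular sources


def read_institution_map(source) -> dict[str, tuple[str, str | None]]:
    """Read an institution -> (country, region) mapping table (CSV)."""
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source, keep_default_na=False)
    out: dict[str, tuple[str, str | None]] = {}
    for row in df.itertuples(index=False):
        region = str(row.region) if str(getattr(row, "region", "")) else None
        out[str(row.institution)] = (str(row.country), region)
    return out


_YEAR = re.compile(r"\b((?:18|19|20)\d{2})\b")


def _year_from(value: str | None) -> int | None:
    if not value:
        return None
    m = _YEAR.search(str(value))
    return int(m.group(1)) if m else None


def _read_table(source) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        return source.copy()
    if isinstance(source, str) and "\t" in source:
        source = io.StringIO(source)
    return pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)


_BOLD_COLUMNS = {
    "phylum_name": "phylum_division",
    "class_name": "class_",
    "order_name": "order",
    "family_name": "family",
    "genus_name": "genus",
    "species_name": "species",
    "country": "country",
    "province_state": "declared_province",
    "exactsite": "locality_text",
    "institution_storing": "storing_institution",
    "copyright_institutions": "copyright_institution",
    "markercode": "marker_raw",
}


def read_bold(
    source, institution_map: dict[str, tuple[str, str | None]] | None = None
) -> list[BarcodeRecord]:
    """Read a BOLD-style public-data export into barcode records.

    Requires a ``processid`` column; unknown columns are ignored.  When an
    institution map is supplied, copyright/storing countries are filled from
    the mapped institution names.
    """
    df = _read_table(source)
    if "processid" not in df.columns:
        raise SchemaError("BOLD table lacks mandatory 'processid' column")
    records: list[BarcodeRecord] = []
    for row in df.to_dict("records"):
        rec = BarcodeRecord(
            record_id=row["processid"] or None, source_db="bold"
        )
        for src, dst in _BOLD_COLUMNS.items():
            value = row.get(src) or None
            if value is not None:
                setattr(rec, dst, value)
        lat, lon = row.get("lat") or None, row.get("lon") or None
        try:
            if lat is not None and lon is not None:
                latf, lonf = float(lat), float(lon)
                if -90 <= latf <= 90 and -180 <= lonf <= 180:
                    rec.latitude, rec.longitude = latf, lonf
        except ValueError:
            pass
        rec.collection_year = _year_from(row.get("collectiondate"))
        rec.submission_year = _year_from(row.get("run_date"))
        if institution_map:
            if rec.copyright_institution in institution_map:
                rec.copyright_country = institution_map[
                    rec.copyright_institution
                ][0]
            if rec.storing_institution in institution_map:
                rec.storing_country = institution_map[rec.storing_institution][0]
        records.append(rec)
    return records


_OCCURRENCE_REQUIRED = (
    "kingdom",
    "phylum",
    "class",
    "order",
    "family",
    "species",
)
_KINGDOMS = {"animalia": "animal", "plantae": "plant"}


def read_occurrences(source) -> list[OccurrenceRecord]:
    """Read a Darwin-Core style occurrence table.

    Rows whose kingdom is neither Animalia nor Plantae are dropped with a
    logged count.
    """
    df = _read_table(source)
    missing = [c for c in _OCCURRENCE_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"occurrence table lacks columns: {missing}")
    records: list[OccurrenceRecord] = []
    dropped = 0
    for row in df.to_dict("records"):
        kingdom = _KINGDOMS.get(str(row.get("kingdom", "")).strip().casefold())
        if kingdom is None:
            dropped += 1
            continue
        rec = OccurrenceRecord(
            occurrence_id=row.get("occurrenceID") or None,
            kingdom=kingdom,
            phylum_division=row.get("phylum") or None,
            class_=row.get("class") or None,
            order=row.get("order") or None,
            family=row.get("family") or None,
            genus=row.get("genus") or None,
            species=row.get("species") or None,
            locality_text=row.get("locality") or None,
            province=row.get("stateProvince") or None,
            municipality=row.get("municipality") or None,
            country=row.get("country") or None,
        )
        try:
            lat = float(row.get("decimalLatitude") or "")
            lon = float(row.get("decimalLongitude") or "")
            if -90 <= lat <= 90 and -180 <= lon <= 180:
                rec.latitude, rec.longitude = lat, lon
        except ValueError:
            pass
        records.append(rec)
    if dropped:
        logger.info("dropped %d occurrence rows outside animal/plant", dropped)
    return records


# ---------------------------------------------------------------------------
# Harmonization


def harmonize(
    genbank_records: list[BarcodeRecord], bold_records: list[BarcodeRecord]
) -> pd.DataFrame:
    """Stack GenBank and BOLD records into one table with unified attribution.

    For GenBank records the copyright fields mirror the publishing fields;
    BOLD records keep their copyright columns.
    """
    gb = records_to_frame(genbank_records)
    bd = records_to_frame(bold_records)
    if len(gb):
        gb["copyright_institution"] = gb["publishing_institution"]
        gb["copyright_country"] = gb["publishing_country"]
    df = pd.concat([gb, bd], ignore_index=True)
    return df


def attribute_contributors(
    records: pd.DataFrame,
    institution_map: dict[str, tuple[str, str | None]],
) -> pd.DataFrame:
    """Fill publishing/copyright/storing countries from the institution map.

    Present values are never overwritten; unmapped institutions stay absent
    (reported as Unknown contributors downstream).
    """
    out = records.copy()
    country_of = {k: v[0] for k, v in institution_map.items()}
    for inst_col, country_col in (
        ("publishing_institution", "publishing_country"),
        ("copyright_institution", "copyright_country"),
        ("storing_institution", "storing_country"),
    ):
        mask = out[country_col].isna() & out[inst_col].notna()
        out.loc[mask, country_col] = out.loc[mask, inst_col].map(country_of)
    return out
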