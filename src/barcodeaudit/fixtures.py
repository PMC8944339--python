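"""Synthetic input corpora with a ground-truth ledger.

Real barcode-audit inputs are live database exports (GenBank flat files, a
BOLD public-data table, a Darwin-Core occurrence table) joined with a
national gazetteer and province boundaries.  This module emits
standards-faithful synthetic versions of all six inputs with *planted*
structure -- missingness rates, locality issue types, taxon-abundance skew,
province sampling skew, contributor-country mix, collection/submission-year
ranges -- and records every planted value and every degradation in a
TruthLedger, which downstream tests treat as the oracle.

The generated geography is a grid of rectangular province polygons separated
by open "sea"; marine records are displaced outside their province polygon
and the ledger stores the brute-force-verified nearest-centroid province.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, box

from ._text import damerau_levenshtein, edit_threshold, normalize_name
from .gazetteer import Gazetteer, GazetteerEntry
from .geometry import ProvinceGeometries, haversine_km

# ---------------------------------------------------------------------------
# Taxon pool

ISSUE_FIELD_ORDER = (
    "coordinates",
    "locality_text",
    "collection_year",
    "submission_year",
    "institution",
    "country",
)

RANKS = ("phylum_division", "class", "order", "family", "genus")


@dataclass(frozen=True)
class TaxonPoolEntry:
    kingdom: str
    phylum_division: str
    class_: str
    order: str
    family: str
    genus: str
    species: str  # full binomial
    weight_barcode: float
    weight_occurrence: float


def _t(kingdom, phylum, cls, order, family, genus, epithet, wb, wo):
    return TaxonPoolEntry(
        kingdom, phylum, cls, order, family, genus, f"{genus} {epithet}", wb, wo
    )


# Skewed pool: Chordata-heavy animal side, vascular-plant-heavy plant side;
# a few occurrence-only taxa (no barcodes) and barcode-only orders/families
# (zero occurrence species, the undefined-ratio case).
DEFAULT_TAXON_POOL: tuple[TaxonPoolEntry, ...] = (
    _t("animal", "Chordata", "Actinopterygii", "Perciformes", "Serranidae", "Epinephelus", "coioides", 12, 10),
    _t("animal", "Chordata", "Actinopterygii", "Perciformes", "Serranidae", "Epinephelus", "lanceolatus", 6, 5),
    _t("animal", "Chordata", "Actinopterygii", "Perciformes", "Labridae", "Cheilinus", "undulatus", 5, 6),
    _t("animal", "Chordata", "Actinopterygii", "Siluriformes", "Clariidae", "Clarias", "batrachus", 4, 4),
    _t("animal", "Chordata", "Amphibia", "Anura", "Ranidae", "Pulchrana", "similis", 3, 3),
    _t("animal", "Chordata", "Mammalia", "Rodentia", "Muridae", "Apomys", "datae", 2, 2),
    _t("animal", "Chordata", "Aves", "Passeriformes", "Zosteropidae", "Zosterops", "montanus", 2, 3),
    _t("animal", "Arthropoda", "Insecta", "Coleoptera", "Carabidae", "Pheropsophus", "occipitalis", 3, 6),
    _t("animal", "Arthropoda", "Insecta", "Lepidoptera", "Nymphalidae", "Ideopsis", "juventa", 3, 7),
    _t("animal", "Arthropoda", "Malacostraca", "Decapoda", "Portunidae", "Portunus", "pelagicus", 4, 5),
    _t("animal", "Mollusca", "Gastropoda", "Neogastropoda", "Conidae", "Conus", "magus", 5, 4),
    _t("animal", "Mollusca", "Gastropoda", "Neogastropoda", "Conidae", "Conus", "striatus", 3, 2),
    _t("animal", "Mollusca", "Bivalvia", "Venerida", "Veneridae", "Paphia", "textile", 2, 3),
    # barcode-only animal order/family (undefined pct_barcoded case)
    _t("animal", "Mollusca", "Gastropoda", "Seguenziida", "Seguenziidae", "Seguenzia", "monocingulata", 2, 0),
    _t("animal", "Annelida", "Polychaeta", "Phyllodocida", "Nereididae", "Perinereis", "nuntia", 1, 3),
    _t("animal", "Echinodermata", "Asteroidea", "Valvatida", "Oreasteridae", "Protoreaster", "nodosus", 2, 3),
    _t("animal", "Cnidaria", "Anthozoa", "Scleractinia", "Acroporidae", "Acropora", "millepora", 2, 4),
    _t("animal", "Cnidaria", "Anthozoa", "Scleractinia", "Acroporidae", "Acropora", "tenuis", 1, 3),
    # occurrence-only animal phyla (documented but never barcoded)
    _t("animal", "Rotifera", "Eurotatoria", "Ploima", "Brachionidae", "Brachionus", "plicatilis", 0, 2),
    _t("animal", "Bryozoa", "Gymnolaemata", "Cheilostomatida", "Bugulidae", "Bugula", "neritina", 0, 1),
    _t("plant", "Tracheophyta", "Magnoliopsida", "Gentianales", "Rubiaceae", "Ixora", "philippinensis", 3, 4),
    _t("plant", "Tracheophyta", "Magnoliopsida", "Fabales", "Fabaceae", "Pterocarpus", "indicus", 3, 4),
    # occurrence-only plant family
    _t("plant", "Tracheophyta", "Magnoliopsida", "Malvales", "Dipterocarpaceae", "Shorea", "contorta", 0, 3),
    _t("plant", "Tracheophyta", "Liliopsida", "Poales", "Poaceae", "Bambusa", "blumeana", 2, 3),
    _t("plant", "Tracheophyta", "Polypodiopsida", "Polypodiales", "Pteridaceae", "Pteris", "vittata", 1, 2),
    _t("plant", "Rhodophyta", "Florideophyceae", "Gracilariales", "Gracilariaceae", "Gracilaria", "salicornia", 2, 2),
    # barcode-only plant order/family (undefined pct_barcoded case)
    _t("plant", "Rhodophyta", "Florideophyceae", "Nemastomatales", "Schizymeniaceae", "Titanophora", "weberae", 1, 0),
    _t("plant", "Chlorophyta", "Ulvophyceae", "Ulvales", "Ulvaceae", "Ulva", "lactuca", 2, 3),
    # occurrence-only plant division
    _t("plant", "Bryophyta", "Bryopsida", "Funariales", "Funariaceae", "Physcomitrium", "eurystomum", 0, 1),
)

HOMO_TAXON = TaxonPoolEntry(
    "animal", "Chordata", "Mammalia", "Primates", "Hominidae",
    "Homo", "Homo sapiens", 0, 0,
)

RAW_MARKER_SPELLINGS: dict[str, tuple[str, ...]] = {
    "COI": (
        "COI",
        "cox1",
        "COI-5P",
        "cytochrome oxidase subunit I",
        "cytochrome c oxidase subunit 1",
    ),
    "CYTB": ("cytb", "cyt b", "cytochrome b"),
    "rbcL": ("rbcL", "RuBisCO", "ribulose-1,5-bisphosphate carboxylase"),
    "matK": ("matK", "maturase K", "MaturaseK"),
    "ITS2": ("ITS2", "internal transcribed spacer 2", "ITS"),
    "OTHER": (
        "16S ribosomal RNA",
        "18S ribosomal RNA",
        "control region",
        "microsatellite",
    ),
}

FOREIGN_PLACE_CANDIDATES = (
    "Sabah",
    "Kota Kinabalu",
    "Sulawesi",
    "Kalimantan",
    "Okinawa",
    "Phuket",
    "Taipei",
    "Johor",
)

FOREIGN_COUNTRIES = ("Malaysia", "Indonesia", "Taiwan", "Thailand")

# institution name -> (country, weight within country)
_INSTITUTIONS: tuple[tuple[str, str, float], ...] = (
    ("University of the Philippines Marine Science Institute", "Philippines", 0.45),
    ("National Museum of Natural History Manila", "Philippines", 0.25),
    ("Central Luzon State University", "Philippines", 0.20),
    ("Mindanao State University Naawan", "Philippines", 0.10),
    ("Smithsonian Institution", "United States", 0.6),
    ("University of Kansas Biodiversity Institute", "United States", 0.4),
    ("Zoologische Staatssammlung Muenchen", "Germany", 1.0),
    ("Centre for Biodiversity Genomics Guelph", "Canada", 1.0),
    ("Kyoto University Museum", "Japan", 1.0),
    ("Australian Museum Sydney", "Australia", 1.0),
    ("Institute of Oceanology Qingdao", "China", 1.0),
    ("Museum National d'Histoire Naturelle Paris", "France", 1.0),
)

_AUTHORS = (
    "Reyes,M.L.", "Santos,J.P.", "Tan,K.", "Garcia,A.", "Miller,S.",
    "Nakamura,H.", "Schmidt,E.", "Cruz,R.D.", "Lee,W.", "Johnson,T.",
)


# ---------------------------------------------------------------------------
# Configuration


def _default_missing_rates() -> dict[str, float]:
    return {
        "coordinates": 0.65,
        "locality_text": 0.45,
        "collection_year": 0.70,
        "submission_year": 0.22,
        "institution": 0.18,
        "country": 0.18,
    }


def _default_issue_mix() -> dict[str, float]:
    return {
        "none": 0.45,
        "unspecified": 0.20,
        "misspelled": 0.10,
        "unknown": 0.10,
        "multiple": 0.07,
        "mismatch": 0.05,
        "mixed": 0.03,
    }


def _default_marker_mix() -> dict[str, float]:
    return {
        "COI": 0.62,
        "CYTB": 0.08,
        "rbcL": 0.10,
        "matK": 0.07,
        "ITS2": 0.08,
        "OTHER": 0.05,
    }


def _default_contributor_mix() -> dict[str, float]:
    return {
        "United States": 0.40,
        "Philippines": 0.30,
        "Germany": 0.08,
        "Canada": 0.07,
        "Japan": 0.05,
        "Australia": 0.04,
        "China": 0.03,
        "France": 0.03,
    }


@dataclass
class FixtureConfig:
    """Planted statistical structure of a synthetic corpus."""

    seed: int = 0
    n_genbank: int = 1160
    n_bold: int = 840
    n_occurrence: int = 5000
    missing_rates: dict[str, float] = field(default_factory=_default_missing_rates)
    issue_mix: dict[str, float] = field(default_factory=_default_issue_mix)
    taxon_pool: tuple[TaxonPoolEntry, ...] = DEFAULT_TAXON_POOL
    province_weights: dict[str, float] | None = None
    contributor_mix: dict[str, float] = field(default_factory=_default_contributor_mix)
    year_range_collection: tuple[int, int] = (1990, 2020)
    year_range_submission: tuple[int, int] = (2000, 2020)
    marker_mix: dict[str, float] = field(default_factory=_default_marker_mix)
    frac_unidentified: float = 0.25
    frac_duplicates: float = 0.02
    frac_decoys: float = 0.02
    frac_marine: float = 0.15
    frac_taxonomy_blank: float = 0.18

    def validate(self) -> None:
        if not self.taxon_pool:
            raise ValueError("taxon pool is empty")
        for name, p in self.missing_rates.items():
            if not 0 <= p <= 1:
                raise ValueError(f"missing rate {name}={p} outside [0,1]")
        for fname in (
            "frac_unidentified",
            "frac_duplicates",
            "frac_decoys",
            "frac_marine",
            "frac_taxonomy_blank",
        ):
            v = getattr(self, fname)
            if not 0 <= v <= 1:
                raise ValueError(f"{fname}={v} outside [0,1]")
        for mix_name in ("issue_mix", "contributor_mix", "marker_mix"):
            mix = getattr(self, mix_name)
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{mix_name} sums to {total}, not 1")
            if any(p < 0 for p in mix.values()):
                raise ValueError(f"{mix_name} has a negative probability")
        if self.province_weights is not None:
            total = sum(self.province_weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"province_weights sums to {total}, not 1")
        for rng_name in ("year_range_collection", "year_range_submission"):
            lo, hi = getattr(self, rng_name)
            if lo > hi:
                raise ValueError(f"{rng_name} is empty: ({lo}, {hi})")


# ---------------------------------------------------------------------------
# Gazetteer and geometries

_SYLLABLES = [
    c + v
    for c in "b c d g k l m n p r s t v z".split()
    for v in ("a", "e", "i", "o", "u")
]


def _make_name(rng: np.random.Generator, existing_norm: list[str]) -> str:
    """A pronounceable unique name, OSA distance >= 4 from existing names.

    The separation guarantees that any single-character corruption of one
    name stays uniquely attributable to it under the misspelling threshold.
    """
    for _ in range(5000):
        n_syll = int(rng.integers(3, 6))
        name = "".join(
            _SYLLABLES[int(rng.integers(len(_SYLLABLES)))]
            for _ in range(n_syll)
        ).capitalize()
        norm = normalize_name(name)
        if all(damerau_levenshtein(norm, e) >= 4 for e in existing_norm):
            existing_norm.append(norm)
            return name
    raise RuntimeError("could not generate a sufficiently distinct name")


def make_gazetteer(
    n_regions: int,
    n_provinces_per: int,
    n_municipalities_per: int,
    seed: int,
) -> Gazetteer:
    """Generate a hierarchical region/province/municipality registry.

    Every province carries at least one name variant ("<name> Province") so
    that variant matching and misspelling detection are exercised.
    """
    if min(n_regions, n_provinces_per, n_municipalities_per) < 1:
        raise ValueError("all counts must be >= 1")
    rng = np.random.default_rng(seed)
    norms: list[str] = []
    gaz = Gazetteer([])
    for _ in range(n_regions):
        region = _make_name(rng, norms)
        gaz.add(GazetteerEntry("region", region, None))
        for _ in range(n_provinces_per):
            province = _make_name(rng, norms)
            gaz.add(
                GazetteerEntry(
                    "province",
                    province,
                    region,
                    variants=(f"{province} Province",),
                )
            )
            for _ in range(n_municipalities_per):
                muni = _make_name(rng, norms)
                gaz.add(GazetteerEntry("municipality", muni, province))
    return gaz


def make_geometries(gazetteer: Gazetteer, seed: int) -> ProvinceGeometries:
    """Lay one 1x1-degree rectangle per province on a 2-degree grid.

    Rectangles are disjoint and the gaps between them are open sea, so
    offshore (marine) sampling points exist by construction.
    """
    provinces = gazetteer.names("province")
    if not provinces:
        raise ValueError("gazetteer has no provinces")
    n_cols = max(1, math.ceil(math.sqrt(len(provinces))))
    lon0, lat0 = 117.0, 5.0
    polys = {}
    for i, name in enumerate(provinces):
        r, c = divmod(i, n_cols)
        x = lon0 + c * 2.0
        y = lat0 + r * 2.0
        polys[name] = box(x, y, x + 1.0, y + 1.0)
    return ProvinceGeometries(polys)


# ---------------------------------------------------------------------------
# Corpus


@dataclass
class Corpus:
    """A generated input bundle plus its ground-truth ledger."""

    genbank_text: str
    bold: pd.DataFrame
    occurrences: pd.DataFrame
    institution_map: pd.DataFrame
    foreign_places: list[str]
    ledger: pd.DataFrame
    gazetteer: Gazetteer
    geometries: ProvinceGeometries

    def write(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "genbank.gb").write_text(self.genbank_text)
        self.bold.to_csv(out / "bold.tsv", sep="\t", index=False)
        self.occurrences.to_csv(out / "occurrences.tsv", sep="\t", index=False)
        self.institution_map.to_csv(out / "institutions.csv", index=False)
        pd.DataFrame({"place": self.foreign_places}).to_csv(
            out / "foreign_places.csv", index=False
        )
        self.ledger.to_csv(out / "ledger.csv", index=False)
        self.gazetteer.to_csv(out / "gazetteer.csv")
        self.geometries.to_geojson(out / "geometries.geojson")


def _weighted_choice(rng, items, weights):
    w = np.asarray(weights, dtype=float)
    return items[int(rng.choice(len(items), p=w / w.sum()))]


def _corrupt_name(rng, name: str, gazetteer: Gazetteer) -> str:
    """One-character corruption of a canonical name, verified recoverable."""
    letters = "abcdefghijklmnopqrstuvwxyz"
    for _ in range(100):
        op = int(rng.integers(4))
        i = int(rng.integers(len(name)))
        if op == 0:  # substitute
            ch = letters[int(rng.integers(26))]
            cand = name[:i] + ch + name[i + 1 :]
        elif op == 1:  # delete
            cand = name[:i] + name[i + 1 :]
        elif op == 2:  # insert
            ch = letters[int(rng.integers(26))]
            cand = name[:i] + ch + name[i:]
        else:  # transpose
            if i >= len(name) - 1:
                continue
            cand = name[:i] + name[i + 1] + name[i] + name[i + 2 :]
        norm = normalize_name(cand)
        if gazetteer.lookup(norm) is not None:
            continue
        if gazetteer.fuzzy_lookup(norm) == ("province", name):
            return cand
    raise RuntimeError(f"could not corrupt {name!r} recoverably")


def _verify_unmatchable(token: str, gazetteer: Gazetteer) -> bool:
    """Token matches nothing exactly and nothing within the fuzzy threshold."""
    norm = normalize_name(token)
    if gazetteer.lookup(norm) is not None:
        return False
    for e in gazetteer.entries:
        for alias in (e.name, *e.variants):
            alias_norm = normalize_name(alias)
            if damerau_levenshtein(norm, alias_norm) <= edit_threshold(
                alias_norm
            ):
                return False
    return True


def _build_locality(rng, issue, province, municipality, gazetteer):
    """Locality text whose planted issue category is mechanically detectable."""
    provinces = gazetteer.names("province")
    if issue == "none":
        return f"{province}, {municipality}"
    if issue == "misspelled":
        return f"{_corrupt_name(rng, province, gazetteer)}, {municipality}"
    if issue == "multiple":
        other = _weighted_choice(
            rng, [p for p in provinces if p != province],
            [1] * (len(provinces) - 1),
        )
        return f"{province} and {other}"
    if issue == "mismatch":
        other = _weighted_choice(
            rng, [p for p in provinces if p != province],
            [1] * (len(provinces) - 1),
        )
        wrong_muni = _weighted_choice(
            rng, gazetteer.children("province", other),
            [1] * len(gazetteer.children("province", other)),
        )
        return f"{province}, {wrong_muni}"
    if issue == "unspecified":
        return gazetteer.region_of_province(province)
    if issue == "unknown":
        for _ in range(20):
            text = f"station {int(rng.integers(1, 99))}"
            if _verify_unmatchable(text, gazetteer):
                return text
        return f"zzq site {int(rng.integers(1, 99))}"
    if issue == "mixed":
        other = _weighted_choice(
            rng, [p for p in provinces if p != province],
            [1] * (len(provinces) - 1),
        )
        return f"{_corrupt_name(rng, province, gazetteer)}, {other}"
    raise ValueError(f"unknown issue {issue!r}")


def _land_point(rng, poly) -> tuple[float, float]:
    minx, miny, maxx, maxy = poly.bounds
    lon = float(rng.uniform(minx + 0.02, maxx - 0.02))
    lat = float(rng.uniform(miny + 0.02, maxy - 0.02))
    return round(lat, 4), round(lon, 4)


def _marine_point(rng, province, geometries) -> tuple[float, float] | None:
    """A point outside every polygon whose nearest centroid is ``province``.

    Verified by brute force over all province centroids; None when no
    suitable point is found (caller falls back to a land point).
    """
    poly = geometries.polygon(province)
    minx, miny, maxx, maxy = poly.bounds
    for _ in range(25):
        side = int(rng.integers(4))
        off = float(rng.uniform(0.08, 0.42))
        along = float(rng.uniform(0.1, 0.9))
        if side == 0:  # north
            lat, lon = maxy + off, minx + along * (maxx - minx)
        elif side == 1:  # south
            lat, lon = miny - off, minx + along * (maxx - minx)
        elif side == 2:  # east
            lat, lon = miny + along * (maxy - miny), maxx + off
        else:  # west
            lat, lon = miny + along * (maxy - miny), minx - off
        lat, lon = round(lat, 4), round(lon, 4)
        pt = Point(lon, lat)
        if any(p.covers(pt) for _, p in geometries.items()):
            continue
        dists = sorted(
            (haversine_km(lat, lon, *geometries.centroid(name)), name)
            for name in geometries.provinces
        )
        if dists[0][1] == province and dists[0][0] < dists[1][0] - 1e-6:
            return lat, lon
    return None


_MONTHS_UP = "JAN FEB MAR APR MAY JUN JUL AUG SEP OCT NOV DEC".split()
_MONTHS_TITLE = [m.capitalize() for m in _MONTHS_UP]


def _format_origin(seq: str) -> str:
    lines = []
    for start in range(0, len(seq), 60):
        chunk = seq[start : start + 60]
        groups = " ".join(
            chunk[i : i + 10] for i in range(0, len(chunk), 10)
        )
        lines.append(f"{start + 1:>9} {groups}")
    return "\n".join(lines)


def _wrap_lineage(parts: list[str], width: int = 58) -> str:
    text = "; ".join(parts) + "."
    lines: list[str] = []
    cur = ""
    for word in text.split(" "):
        if cur and len(cur) + 1 + len(word) > width:
            lines.append(cur)
            cur = word
        else:
            cur = f"{cur} {word}".strip()
    if cur:
        lines.append(cur)
    return "\n".join(" " * 12 + ln for ln in lines)


def _genbank_entry(rec: dict, rng: np.random.Generator) -> str:
    """Render one planted record as a GenBank flat-file entry."""
    seq = rec["sequence"]
    length = len(seq)
    species = rec["species_label"]
    sub_year = rec.get("submission_year")
    institution = rec.get("institution")
    locus_date = (
        f"01-{_MONTHS_UP[int(rng.integers(12))]}-{sub_year}"
        if sub_year
        else "01-JAN-2021"
    )
    division = "INV" if rec["kingdom"] == "animal" else "PLN"
    kingdom_marker = "Metazoa" if rec["kingdom"] == "animal" else "Viridiplantae"
    ranks = [rec.get(r) for r in RANKS]
    lineage = ["Eukaryota", kingdom_marker]
    if all(r is not None for r in ranks):
        lineage += ranks
    lines = [
        f"LOCUS       {rec['record_id']:<12}{length:>16} bp    DNA     "
        f"linear   {division} {locus_date}",
        f"DEFINITION  {rec['definition']}",
        f"ACCESSION   {rec['record_id']}",
        f"VERSION     {rec['record_id']}.1",
        f"SOURCE      {species}",
        f"  ORGANISM  {species}",
        _wrap_lineage(lineage),
        f"REFERENCE   1  (bases 1 to {length})",
        f"  AUTHORS   {rec['author']}",
        "  TITLE     Direct Submission",
    ]
    street = f"{int(rng.integers(1, 99))} Research Drive"
    if sub_year is not None:
        day = int(rng.integers(1, 29))
        mon = _MONTHS_UP[int(rng.integers(12))]
        stamp = f"{day:02d}-{mon}-{sub_year}"
        if institution is not None:
            lines.append(
                f"  JOURNAL   Submitted ({stamp}) {institution}, {street}"
            )
        else:
            lines.append(f"  JOURNAL   Submitted ({stamp})")
    elif institution is not None:
        lines.append(f"  JOURNAL   {institution}, {street}")
    else:
        lines.append("  JOURNAL   Unpublished")
    lines += [
        "FEATURES             Location/Qualifiers",
        f"     source          1..{length}",
        f'                     /organism="{species}"',
    ]
    if rec.get("country") is not None:
        value = rec["country"]
        if rec.get("locality_text") is not None:
            value = f"{value}: {rec['locality_text']}"
        lines.append(f'                     /country="{value}"')
    if rec.get("latitude") is not None:
        lines.append(
            f'                     /lat_lon="{rec["latitude"]:.4f} N '
            f'{rec["longitude"]:.4f} E"'
        )
    if rec.get("collection_year") is not None:
        year = rec["collection_year"]
        form = int(rng.integers(4))
        mon = _MONTHS_TITLE[int(rng.integers(12))]
        day = int(rng.integers(1, 29))
        if form == 0:
            date = f"{year}"
        elif form == 1:
            date = f"{mon}-{year}"
        elif form == 2:
            date = f"{day:02d}-{mon}-{year}"
        else:
            date = f"{year}-{int(rng.integers(1, 13)):02d}-{day:02d}"
        lines.append(f'                     /collection_date="{date}"')
    placement = rec["marker_placement"]
    if placement == "gene":
        lines += [
            f"     gene            <1..>{length}",
            f'                     /gene="{rec["marker_raw_spelling"]}"',
        ]
    elif placement == "product":
        lines += [
            f"     CDS             <1..>{length}",
            f'                     /product="{rec["marker_raw_spelling"]}"',
        ]
    lines.append("ORIGIN      ")
    lines.append(_format_origin(seq))
    lines.append("//")
    return "\n".join(lines) + "\n"


def generate_corpus(
    config: FixtureConfig,
    gazetteer: Gazetteer,
    geometries: ProvinceGeometries,
) -> Corpus:
    """Emit the six synthetic inputs plus the TruthLedger.

    Base records number ``n_genbank + n_bold``; planted duplicates and decoy
    records (foreign-country, foreign-locality-mismatch, Homo sapiens) are
    emitted on top of the base counts and flagged in the ledger.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    provinces = gazetteer.names("province")
    regions = gazetteer.names("region")
    if config.province_weights is None:
        w = np.array([1.0 / (i + 1) for i in range(len(provinces))])
        province_weights = dict(zip(provinces, w / w.sum()))
    else:
        province_weights = config.province_weights
    prov_names = list(province_weights)
    prov_w = [province_weights[p] for p in prov_names]

    # institutions, with Philippine ones spread over the first three regions
    inst_rows = []
    ph_regions = [regions[0], regions[0], regions[min(1, len(regions) - 1)],
                  regions[min(2, len(regions) - 1)]]
    ph_i = 0
    for name, country, weight in _INSTITUTIONS:
        region = ""
        if country == "Philippines":
            region = ph_regions[ph_i % len(ph_regions)]
            ph_i += 1
        inst_rows.append((name, country, region))
    institution_map = pd.DataFrame(
        inst_rows, columns=["institution", "country", "region"]
    )
    inst_by_country: dict[str, list[tuple[str, float, str | None]]] = {}
    for (name, country, weight), (_, _, region) in zip(_INSTITUTIONS, inst_rows):
        inst_by_country.setdefault(country, []).append(
            (name, weight, region or None)
        )

    foreign_places = [
        p for p in FOREIGN_PLACE_CANDIDATES if _verify_unmatchable(p, gazetteer)
    ]
    if not foreign_places:
        raise RuntimeError("no usable foreign place names")

    pool = list(config.taxon_pool)
    wb = np.array([t.weight_barcode for t in pool], dtype=float)
    wo = np.array([t.weight_occurrence for t in pool], dtype=float)
    if wb.sum() <= 0 or wo.sum() <= 0:
        raise ValueError("taxon pool has no barcode or no occurrence weight")
    wb /= wb.sum()
    wo /= wo.sum()

    issue_names = list(config.issue_mix)
    issue_p = np.array([config.issue_mix[k] for k in issue_names])
    marker_names = list(config.marker_mix)
    marker_p = np.array([config.marker_mix[k] for k in marker_names])
    contrib_names = list(config.contributor_mix)
    contrib_p = np.array([config.contributor_mix[k] for k in contrib_names])

    def sample_institution(country):
        insts = inst_by_country.get(country)
        if not insts:
            return f"{country} Institute of Biodiversity", None
        names = [i[0] for i in insts]
        weights = [i[1] for i in insts]
        pick = _weighted_choice(rng, list(range(len(names))), weights)
        return names[pick], insts[pick][2]

    ledger_rows: list[dict] = []
    genbank_entries: list[str] = []
    bold_rows: list[dict] = []
    gb_counter = 0
    bold_counter = 0

    def next_id(source):
        nonlocal gb_counter, bold_counter
        if source == "genbank":
            gb_counter += 1
            return f"SYN{gb_counter:06d}"
        bold_counter += 1
        return f"SYNPH{bold_counter:04d}-20"

    def plant_record(source, decoy_kind=None):
        rec: dict = {
            "record_id": next_id(source),
            "source_db": source,
            "is_decoy": decoy_kind is not None,
            "decoy_kind": decoy_kind,
            "is_duplicate": False,
            "is_unidentified": False,
            "is_marine": False,
            "blanked": [],
        }
        if decoy_kind == "homo":
            taxon = HOMO_TAXON
        else:
            taxon = pool[int(rng.choice(len(pool), p=wb))]
        rec.update(
            kingdom=taxon.kingdom,
            phylum_division=taxon.phylum_division,
            **{"class": taxon.class_},
            order=taxon.order,
            family=taxon.family,
            genus=taxon.genus,
            species_true=taxon.species,
        )
        rec["species_label"] = taxon.species
        if decoy_kind is None and rng.random() < config.frac_unidentified:
            rec["species_label"] = f"{taxon.genus} sp."
            rec["is_unidentified"] = True

        marker = _weighted_choice(rng, marker_names, marker_p)
        spellings = RAW_MARKER_SPELLINGS[marker]
        spelling = spellings[int(rng.integers(len(spellings)))]
        rec["marker"] = marker
        rec["marker_raw_spelling"] = spelling
        rec["marker_placement"] = (
            ("gene", "product", "definition")[int(rng.integers(3))]
            if source == "genbank"
            else "column"
        )
        rec["definition"] = (
            f"{rec['species_label']} {spelling} gene, partial sequence."
        )

        seq_len = int(rng.integers(420, 781))
        rec["sequence"] = "".join(
            "acgt"[i] for i in rng.integers(0, 4, size=seq_len)
        )

        province = _weighted_choice(rng, prov_names, prov_w)
        municipality = _weighted_choice(
            rng,
            gazetteer.children("province", province),
            [1] * len(gazetteer.children("province", province)),
        )
        rec["province"] = province
        rec["municipality"] = municipality
        rec["sampled_region"] = gazetteer.region_of_province(province)

        if decoy_kind in ("foreign_country", "foreign_mismatch"):
            rec["province"] = None
            rec["municipality"] = None
            rec["sampled_region"] = None
            rec["latitude"] = None
            rec["longitude"] = None
            if decoy_kind == "foreign_country":
                rec["country"] = FOREIGN_COUNTRIES[
                    int(rng.integers(len(FOREIGN_COUNTRIES)))
                ]
                rec["locality_text"] = None
                rec["issue"] = None
            else:
                rec["country"] = "Philippines"
                rec["locality_text"] = foreign_places[
                    int(rng.integers(len(foreign_places)))
                ]
                rec["issue"] = "unknown"
        else:
            rec["country"] = "Philippines"
            if rng.random() < config.frac_marine:
                pt = _marine_point(rng, province, geometries)
                if pt is not None:
                    rec["is_marine"] = True
            if rec["is_marine"]:
                rec["latitude"], rec["longitude"] = pt
            else:
                rec["latitude"], rec["longitude"] = _land_point(
                    rng, geometries.polygon(province)
                )
            issue = _weighted_choice(rng, issue_names, issue_p)
            rec["issue"] = issue
            rec["locality_text"] = _build_locality(
                rng, issue, province, municipality, gazetteer
            )

        lo, hi = config.year_range_collection
        rec["collection_year"] = int(rng.integers(lo, hi + 1))
        lo, hi = config.year_range_submission
        rec["submission_year"] = int(rng.integers(lo, hi + 1))

        country_c = _weighted_choice(rng, contrib_names, contrib_p)
        inst, inst_region = sample_institution(country_c)
        rec["institution"] = inst
        rec["contributor_country"] = country_c
        rec["contributor_region"] = inst_region
        rec["author"] = _AUTHORS[int(rng.integers(len(_AUTHORS)))]

        if decoy_kind is None:
            # degradation: blank fields at the planted rates
            for fname in ISSUE_FIELD_ORDER:
                if rng.random() < config.missing_rates.get(fname, 0.0):
                    rec["blanked"].append(fname)
            if source == "genbank" and "country" in rec["blanked"]:
                if "locality_text" not in rec["blanked"]:
                    rec["blanked"].append("locality_text")
            if rng.random() < config.frac_taxonomy_blank:
                if source == "genbank":
                    rec["blanked"].extend(RANKS)
                else:
                    n_blank = int(rng.integers(1, len(RANKS) + 1))
                    picked = rng.choice(
                        len(RANKS), size=n_blank, replace=False
                    )
                    rec["blanked"].extend(RANKS[i] for i in sorted(picked))
        return rec

    def degrade(rec):
        """Apply the planted blanks, returning the emission-ready view."""
        out = dict(rec)
        blanked = set(rec["blanked"])
        if "coordinates" in blanked:
            out["latitude"] = None
            out["longitude"] = None
        if "locality_text" in blanked:
            out["locality_text"] = None
            out["issue"] = None
        if "collection_year" in blanked:
            out["collection_year"] = None
        if "submission_year" in blanked:
            out["submission_year"] = None
        if "institution" in blanked:
            out["institution"] = None
        if "country" in blanked:
            out["country"] = None
        for rank in RANKS:
            if rank in blanked:
                out[rank] = None
        return out

    def emit(rec):
        view = degrade(rec)
        if rec["source_db"] == "genbank":
            genbank_entries.append(_genbank_entry(view, rng))
        else:
            declared = ""
            if view["locality_text"] is not None and view["issue"] in (
                "none",
                "misspelled",
            ):
                declared = view["province"]
            bold_rows.append(
                {
                    "processid": view["record_id"],
                    "sampleid": view["record_id"].replace("-20", ""),
                    "phylum_name": view["phylum_division"] or "",
                    "class_name": view["class"] or "",
                    "order_name": view["order"] or "",
                    "family_name": view["family"] or "",
                    "genus_name": view["genus"] or "",
                    "species_name": view["species_label"] or "",
                    "lat": (
                        f"{view['latitude']:.4f}"
                        if view["latitude"] is not None
                        else ""
                    ),
                    "lon": (
                        f"{view['longitude']:.4f}"
                        if view["longitude"] is not None
                        else ""
                    ),
                    "country": view["country"] or "",
                    "province_state": declared or "",
                    "exactsite": view["locality_text"] or "",
                    "institution_storing": view["institution"] or "",
                    "copyright_institutions": view["institution"] or "",
                    "markercode": view["marker_raw_spelling"],
                    "collectiondate": (
                        str(view["collection_year"])
                        if view["collection_year"] is not None
                        else ""
                    ),
                    "run_date": (
                        str(view["submission_year"])
                        if view["submission_year"] is not None
                        else ""
                    ),
                }
            )
        view_blanked = set(rec["blanked"])
        ledger_rows.append(
            {
                "record_id": rec["record_id"],
                "source_db": rec["source_db"],
                "kingdom": rec["kingdom"],
                "phylum_division": rec["phylum_division"],
                "class": rec["class"],
                "order": rec["order"],
                "family": rec["family"],
                "genus": rec["genus"],
                "species_true": rec["species_true"],
                "species_label": rec["species_label"],
                "marker": rec["marker"],
                "marker_raw": rec["marker_raw_spelling"],
                "marker_placement": rec["marker_placement"],
                "country": rec["country"],
                "latitude": rec["latitude"],
                "longitude": rec["longitude"],
                "locality_text": rec["locality_text"],
                "province": rec["province"],
                "municipality": rec["municipality"],
                "sampled_region": rec["sampled_region"],
                "is_marine": rec["is_marine"],
                "collection_year": rec["collection_year"],
                "submission_year": rec["submission_year"],
                "institution": rec["institution"],
                "contributor_country": rec["contributor_country"],
                "contributor_region": rec["contributor_region"],
                "issue": rec["issue"] if "locality_text" not in view_blanked else None,
                "blanked_fields": ";".join(rec["blanked"]),
                "is_duplicate": rec["is_duplicate"],
                "is_decoy": rec["is_decoy"],
                "decoy_kind": rec["decoy_kind"],
                "is_unidentified": rec["is_unidentified"],
            }
        )

    decoy_kinds = ("homo", "foreign_country", "foreign_mismatch")
    for source, count in (("genbank", config.n_genbank), ("bold", config.n_bold)):
        for _ in range(count):
            rec = plant_record(source)
            emit(rec)
            if rng.random() < config.frac_duplicates:
                dup = dict(rec)
                dup["is_duplicate"] = True
                emit(dup)
            if rng.random() < config.frac_decoys:
                kind = decoy_kinds[int(rng.integers(3))]
                emit(plant_record(source, decoy_kind=kind))

    # occurrence records
    occ_rows: list[dict] = []
    for i in range(config.n_occurrence):
        occ_id = f"occ{i + 1:06d}"
        decoy = rng.random() < config.frac_decoys
        taxon = HOMO_TAXON if decoy else pool[int(rng.choice(len(pool), p=wo))]
        province = _weighted_choice(rng, prov_names, prov_w)
        municipality = _weighted_choice(
            rng,
            gazetteer.children("province", province),
            [1] * len(gazetteer.children("province", province)),
        )
        lat, lon = _land_point(rng, geometries.polygon(province))
        occ_rows.append(
            {
                "occurrenceID": occ_id,
                "kingdom": "Animalia" if taxon.kingdom == "animal" else "Plantae",
                "phylum": taxon.phylum_division,
                "class": taxon.class_,
                "order": taxon.order,
                "family": taxon.family,
                "genus": taxon.genus,
                "species": taxon.species,
                "decimalLatitude": f"{lat:.4f}",
                "decimalLongitude": f"{lon:.4f}",
                "locality": f"{province}, {municipality}",
                "stateProvince": province,
                "municipality": municipality,
                "country": "Philippines",
            }
        )
        ledger_rows.append(
            {
                "record_id": occ_id,
                "source_db": "occurrence",
                "kingdom": taxon.kingdom,
                "phylum_division": taxon.phylum_division,
                "class": taxon.class_,
                "order": taxon.order,
                "family": taxon.family,
                "genus": taxon.genus,
                "species_true": taxon.species,
                "species_label": taxon.species,
                "marker": None,
                "marker_raw": None,
                "country": "Philippines",
                "latitude": lat,
                "longitude": lon,
                "locality_text": f"{province}, {municipality}",
                "province": province,
                "municipality": municipality,
                "sampled_region": gazetteer.region_of_province(province),
                "is_marine": False,
                "collection_year": None,
                "submission_year": None,
                "institution": None,
                "contributor_country": None,
                "contributor_region": None,
                "issue": None,
                "blanked_fields": "",
                "is_duplicate": False,
                "is_decoy": decoy,
                "decoy_kind": "homo" if decoy else None,
                "is_unidentified": False,
            }
        )

    bold_columns = [
        "processid", "sampleid", "phylum_name", "class_name", "order_name",
        "family_name", "genus_name", "species_name", "lat", "lon", "country",
        "province_state", "exactsite", "institution_storing",
        "copyright_institutions", "markercode", "collectiondate", "run_date",
    ]
    occ_columns = [
        "occurrenceID", "kingdom", "phylum", "class", "order", "family",
        "genus", "species", "decimalLatitude", "decimalLongitude", "locality",
        "stateProvince", "municipality", "country",
    ]
    ledger_columns = [
        "record_id", "source_db", "kingdom", "phylum_division", "class",
        "order", "family", "genus", "species_true", "species_label", "marker",
        "marker_raw", "marker_placement", "country", "latitude", "longitude",
        "locality_text", "province", "municipality", "sampled_region",
        "is_marine", "collection_year", "submission_year", "institution",
        "contributor_country", "contributor_region", "issue",
        "blanked_fields", "is_duplicate", "is_decoy", "decoy_kind",
        "is_unidentified",
    ]
    ledger = pd.DataFrame(ledger_rows, columns=ledger_columns)
    return Corpus(
        genbank_text="".join(genbank_entries),
        bold=pd.DataFrame(bold_rows, columns=bold_columns),
        occurrences=pd.DataFrame(occ_rows, columns=occ_columns),
        institution_map=institution_map,
        foreign_places=foreign_places,
        ledger=ledger,
        gazetteer=gazetteer,
        geometries=geometries,
    )
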