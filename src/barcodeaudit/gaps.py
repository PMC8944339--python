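"""Metadata-completeness quantification and identification-vs-barcoding rates.

Completeness is reported in three categories: publication and records
(collection year, submission year, copyright institution), sampling location
(coordinates, and within the no-coordinate subset the share with descriptive
locality information), and the overall share of records with no location
metadata of any kind.  Locality issues are tabulated over the seven-way
classification.  Per-taxon identification points compare the share of a
taxon's barcode records identified to species against the share of its
occurrence-documented species that have at least one barcode record; the
latter ratio is undefined (NaN) for taxa with no occurrence species, and
such taxa are listed, not dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clean import ISSUE_CATEGORIES

COMPLETENESS_FIELDS = (
    "collection_year",
    "submission_year",
    "copyright_institution",
    "coordinates",
    "any_location_metadata",
)

IDENTIFICATION_RANKS = ("phylum_division", "class", "order", "family")


def _pct(count: int, total: int) -> float:
    return float("nan") if total == 0 else 100.0 * count / total


@dataclass
class CompletenessReport:
    """Missing-metadata counts and percentages for one record set."""

    mode: str
    total: int
    missing: dict[str, int] = field(default_factory=dict)
    no_coords_with_locality: int = 0
    no_coords_without_locality: int = 0

    @property
    def empty(self) -> bool:
        return self.total == 0

    def pct_missing(self, field_name: str) -> float:
        return _pct(self.missing[field_name], self.total)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "mode": self.mode,
                "field": f,
                "n_missing": self.missing[f],
                "pct_missing": round(self.pct_missing(f), 2),
                "total": self.total,
            }
            for f in COMPLETENESS_FIELDS
        ]
        no_coords = self.missing["coordinates"]
        rows.append(
            {
                "mode": self.mode,
                "field": "no_coords_with_descriptive_locality",
                "n_missing": self.no_coords_with_locality,
                "pct_missing": round(_pct(self.no_coords_with_locality, no_coords), 2)
                if no_coords
                else float("nan"),
                "total": no_coords,
            }
        )
        rows.append(
            {
                "mode": self.mode,
                "field": "no_coords_without_descriptive_locality",
                "n_missing": self.no_coords_without_locality,
                "pct_missing": round(
                    _pct(self.no_coords_without_locality, no_coords), 2
                )
                if no_coords
                else float("nan"),
                "total": no_coords,
            }
        )
        return pd.DataFrame(rows)


def _has_descriptive_locality(df: pd.DataFrame) -> pd.Series:
    return (
        df["locality_text"].notna()
        | df["province"].notna()
        | df["municipality"].notna()
        | df["barangay"].notna()
    )


def completeness(records: pd.DataFrame, mode: str) -> CompletenessReport:
    """Count records with missing metadata in each completeness category.

    A record is missing *any* location metadata exactly when its coordinates,
    locality text and all resolved administrative units are absent.
    """
    total = len(records)
    rep = CompletenessReport(mode=mode, total=total)
    if total == 0:
        rep.missing = {f: 0 for f in COMPLETENESS_FIELDS}
        return rep
    no_coords = records["latitude"].isna() | records["longitude"].isna()
    descriptive = _has_descriptive_locality(records)
    rep.missing = {
        "collection_year": int(records["collection_year"].isna().sum()),
        "submission_year": int(records["submission_year"].isna().sum()),
        "copyright_institution": int(
            records["copyright_institution"].isna().sum()
        ),
        "coordinates": int(no_coords.sum()),
        "any_location_metadata": int((no_coords & ~descriptive).sum()),
    }
    rep.no_coords_with_locality = int((no_coords & descriptive).sum())
    rep.no_coords_without_locality = int((no_coords & ~descriptive).sum())
    return rep


def issue_frequencies(records: pd.DataFrame) -> pd.DataFrame:
    """Frequency of each locality-issue category among locality-bearing records."""
    bearing = records[records["locality_text"].notna()]
    counts = bearing["issue"].value_counts()
    rows = [
        {"issue": cat, "count": int(counts.get(cat, 0))}
        for cat in ISSUE_CATEGORIES
    ]
    out = pd.DataFrame(rows)
    assert out["count"].sum() == len(bearing)
    return out


def identification_vs_barcoding(
    barcodes: pd.DataFrame,
    occurrences: pd.DataFrame,
    rank: str,
    bounded: bool = True,
) -> pd.DataFrame:
    """Per-taxon species-identification and species-barcoding percentages.

    For each taxon at ``rank`` present in the barcode data (separately per
    kingdom): ``pct_identified`` is the share of its barcode records whose
    species survives the "sp."/"gen." rule; ``pct_barcoded`` is the share of
    its occurrence-documented species having at least one barcode record.
    With ``bounded`` (default) the barcoded-species numerator is intersected
    with the occurrence species set so the ratio is at most 100; the
    unbounded variant counts all barcoded species.  ``pct_barcoded`` is NaN
    when the taxon has no occurrence species.
    """
    if rank not in IDENTIFICATION_RANKS:
        raise ValueError(f"unsupported rank {rank!r}")
    bar = barcodes[barcodes[rank].notna() & barcodes["kingdom"].notna()]
    occ = occurrences[occurrences[rank].notna()]
    occ_species: dict[tuple[str, str], set[str]] = {
        key: set(grp["species"].dropna())
        for key, grp in occ.groupby(["kingdom", rank])
    }
    rows = []
    for (kingdom, taxon), grp in bar.groupby(["kingdom", rank]):
        n_records = len(grp)
        identified = grp["species"].notna()
        barcoded_species = set(grp.loc[identified, "species"])
        occ_sp = occ_species.get((kingdom, taxon), set())
        if bounded:
            numerator = len(barcoded_species & occ_sp)
        else:
            numerator = len(barcoded_species)
        pct_barcoded = (
            _pct(numerator, len(occ_sp)) if occ_sp else float("nan")
        )
        rows.append(
            {
                "taxon": taxon,
                "rank": rank,
                "kingdom": kingdom,
                "n_barcode_records": n_records,
                "n_identified": int(identified.sum()),
                "pct_identified": round(_pct(int(identified.sum()), n_records), 2),
                "n_occurrence_species": len(occ_sp),
                "n_barcoded_species": numerator,
                "pct_barcoded": (
                    round(pct_barcoded, 2)
                    if not math.isnan(pct_barcoded)
                    else float("nan")
                ),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "taxon",
            "rank",
            "kingdom",
            "n_barcode_records",
            "n_identified",
            "pct_identified",
            "n_occurrence_species",
            "n_barcoded_species",
            "pct_barcoded",
        ],
    )
    return out.sort_values(["kingdom", "taxon"]).reset_index(drop=True)


def undefined_ratio_taxa(points: pd.DataFrame) -> list[str]:
    """Taxa whose barcoded-species ratio is undefined (no occurrence species)."""
    mask = points["pct_barcoded"].isna()
    return points.loc[mask, "taxon"].tolist()
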