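"""Taxonomic and spatial bias tables.

Counts of barcode vs occurrence records per taxon and per province are
log10-transformed (zero counts are assigned -1, since log10 is undefined
there) and flagged against the 5th/95th percentiles of the transformed
values -- the extreme 10% on each axis.  Spatial assignment places a
coordinate in the province polygon containing it, falling back for offshore
(marine) points to the province with the nearest polygon centroid by
great-circle distance.  Contributor attribution uses the copyright country;
temporal trends per contributor class are smoothed with tricube-weighted
local linear regression (loess); the region matrix cross-tabulates the
region of the copyright-holding institution ("processing center") against
the region sampled.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._text import normalize_name
from .gazetteer import Gazetteer
from .geometry import ProvinceGeometries, haversine_km
from shapely.geometry import Point

logger = logging.getLogger(__name__)


def log_with_zero_rule(n: int) -> float:
    """log10 of a count, with zero counts assigned the value -1."""
    if n < 0:
        raise ValueError(f"negative count {n}")
    return math.log10(n) if n >= 1 else -1.0


def add_log_columns(points: pd.DataFrame) -> pd.DataFrame:
    out = points.copy()
    out["log_barcode"] = out["n_barcode"].map(log_with_zero_rule)
    out["log_occurrence"] = out["n_occurrence"].map(log_with_zero_rule)
    return out


def percentile_flags(
    points: pd.DataFrame,
    columns: tuple[str, str] = ("log_barcode", "log_occurrence"),
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Flag points at or beyond the 5th/95th percentiles of each axis.

    Thresholds use the linear-interpolation quantile definition on the
    transformed values; comparisons are inclusive, so a point *at* the 95th
    percentile is flagged high and one at the 5th is flagged low.
    """
    if len(points) == 0:
        raise ValueError("no points to flag")
    out = points.copy()
    thresholds: dict[str, tuple[float, float]] = {}
    for col, tag in zip(columns, ("barcode", "occurrence")):
        values = out[col].to_numpy(dtype=float)
        p5, p95 = np.percentile(values, [5, 95])
        thresholds[tag] = (float(p5), float(p95))
        out[f"high_{tag}"] = out[col] >= p95
        out[f"low_{tag}"] = out[col] <= p5
    return out, thresholds


# ---------------------------------------------------------------------------
# Spatial assignment


def assign_province(
    latitude: float,
    longitude: float,
    geometries: ProvinceGeometries,
) -> tuple[str, str]:
    """Assign a coordinate to a province.

    A point inside a province polygon gets that province (boundary points
    resolve to the first containing polygon in the fixed province order);
    otherwise the nearest polygon centroid by great-circle distance wins,
    with ties broken by lexicographic province name.
    Returns (province, method) with method in {"within", "nearest_centroid"}.
    """
    if len(geometries) == 0:
        raise ValueError("empty geometry set")
    if not (-90 <= latitude <= 90 and -180 <= longitude <= 180):
        raise ValueError(f"coordinates out of bounds: {latitude}, {longitude}")
    pt = Point(longitude, latitude)
    for name, poly in geometries.items():
        if poly.covers(pt):
            return name, "within"
    best = min(
        (
            (haversine_km(latitude, longitude, *geometries.centroid(name)), name)
            for name in geometries.provinces
        ),
        key=lambda t: (t[0], t[1]),
    )
    return best[1], "nearest_centroid"


@dataclass
class ResidueLog:
    """Records excluded from a tally, by reason."""

    counts: dict[str, int]

    def total(self) -> int:
        return sum(self.counts.values())


def effective_provinces(df: pd.DataFrame, geometries: ProvinceGeometries):
    """Province per record: spatial assignment when coordinates exist, else
    the resolved province field.  Returns (provinces, n_without_location)."""
    provinces = []
    n_no_location = 0
    for row in df.itertuples(index=False):
        lat, lon = row.latitude, row.longitude
        if pd.notna(lat) and pd.notna(lon):
            provinces.append(assign_province(lat, lon, geometries)[0])
        elif pd.notna(row.province) and row.province in geometries:
            provinces.append(row.province)
        else:
            provinces.append(None)
            n_no_location += 1
    return provinces, n_no_location


def province_counts(
    barcodes: pd.DataFrame,
    occurrences: pd.DataFrame,
    geometries: ProvinceGeometries,
) -> tuple[pd.DataFrame, ResidueLog]:
    """Per-province record counts for both datasets.

    Records with coordinates are assigned spatially; records without use
    their resolved province; records with neither are excluded and counted
    in the residue log.
    """
    residues = {}
    frames = {}
    for label, df in (("barcode", barcodes), ("occurrence", occurrences)):
        assigned, n_excluded = effective_provinces(df, geometries)
        residues[f"{label}_no_location"] = n_excluded
        frames[label] = pd.Series(
            [p for p in assigned if p is not None], dtype=object
        ).value_counts()
    rows = [
        {
            "province": name,
            "n_barcode": int(frames["barcode"].get(name, 0)),
            "n_occurrence": int(frames["occurrence"].get(name, 0)),
        }
        for name in geometries.provinces
    ]
    return pd.DataFrame(rows), ResidueLog(residues)


def taxon_counts(
    barcodes: pd.DataFrame, occurrences: pd.DataFrame, rank: str
) -> pd.DataFrame:
    """Barcode vs occurrence record counts per taxon at a rank.

    The unit set is the union of taxa seen in either dataset, so taxa with
    zero records on one side appear with a zero count (and get the -1
    transform downstream).
    """
    bar = barcodes[barcodes[rank].notna() & barcodes["kingdom"].notna()]
    occ = occurrences[occurrences[rank].notna() & occurrences["kingdom"].notna()]
    bar_counts = bar.groupby(["kingdom", rank]).size()
    occ_counts = occ.groupby(["kingdom", rank]).size()
    keys = sorted(set(bar_counts.index) | set(occ_counts.index))
    rows = [
        {
            "taxon": taxon,
            "kingdom": kingdom,
            "rank": rank,
            "n_barcode": int(bar_counts.get((kingdom, taxon), 0)),
            "n_occurrence": int(occ_counts.get((kingdom, taxon), 0)),
        }
        for kingdom, taxon in keys
    ]
    return pd.DataFrame(
        rows, columns=["taxon", "kingdom", "rank", "n_barcode", "n_occurrence"]
    )


# ---------------------------------------------------------------------------
# Contributors


def contributor_counts(
    records: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Barcode records per copyright country, plus the local/foreign split.

    Records with no copyright country are reported as Unknown and excluded
    from the two-class (Philippines vs Foreign) percentage.
    """
    country = records["copyright_country"]
    counts = country.value_counts()
    table = pd.DataFrame(
        {
            "country": counts.index,
            "n_records": counts.to_numpy(dtype=int),
        }
    ).sort_values(["n_records", "country"], ascending=[False, True]).reset_index(
        drop=True
    )
    is_ph = country.map(
        lambda c: normalize_name(str(c)) == "philippines"
        if pd.notna(c)
        else None
    )
    n_ph = int((is_ph == True).sum())  # noqa: E712
    n_foreign = int((is_ph == False).sum())  # noqa: E712
    n_unknown = int(country.isna().sum())
    known = n_ph + n_foreign
    split = pd.DataFrame(
        [
            {
                "contributor_class": "Philippines",
                "n_records": n_ph,
                "pct_of_known": round(100.0 * n_ph / known, 2) if known else float("nan"),
            },
            {
                "contributor_class": "Foreign",
                "n_records": n_foreign,
                "pct_of_known": round(100.0 * n_foreign / known, 2)
                if known
                else float("nan"),
            },
            {
                "contributor_class": "Unknown",
                "n_records": n_unknown,
                "pct_of_known": float("nan"),
            },
        ]
    )
    return table, split


def contributor_class(country: str | None) -> str:
    if country is None or (isinstance(country, float) and pd.isna(country)):
        return "Unknown"
    if normalize_name(str(country)) == "philippines":
        return "Philippines"
    return "Foreign"


# ---------------------------------------------------------------------------
# Temporal trends (loess)


def tricube_weights(distances: np.ndarray, bandwidth: float) -> np.ndarray:
    u = np.clip(np.abs(distances) / bandwidth, 0.0, 1.0)
    return (1 - u**3) ** 3


def loess_smooth(
    x: np.ndarray, y: np.ndarray, span: float = 0.75, degree: int = 1
) -> np.ndarray:
    """Locally weighted polynomial regression evaluated at each x.

    For every evaluation point the window covers the ``ceil(span * n)``
    nearest x values (including the point itself); weights are tricube in
    the distance scaled by the window radius.  Degree-1 fits reproduce
    constant and exactly linear series to machine precision.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n == 0:
        return np.array([])
    k = max(degree + 1, int(math.ceil(span * n)))
    k = min(k, n)
    out = np.empty(n)
    for i, x0 in enumerate(x):
        d = np.abs(x - x0)
        idx = np.argsort(d, kind="stable")[:k]
        h = d[idx].max()
        if h == 0:
            out[i] = np.average(y[idx])
            continue
        w = tricube_weights(d[idx], h)
        if (w > 0).sum() <= degree:
            # all window mass on the boundary; fall back to uniform weights
            w = np.ones_like(w)
        sw = np.sqrt(w)
        design = np.vander(x[idx] - x0, degree + 1, increasing=True)
        coef, *_ = np.linalg.lstsq(design * sw[:, None], y[idx] * sw, rcond=None)
        out[i] = coef[0]
    return out


def temporal_trends(
    records: pd.DataFrame,
    axis: str,
    span: float = 0.75,
) -> pd.DataFrame:
    """Yearly record counts per contributor class with a loess curve.

    ``axis`` is ``collection_year`` or ``submission_year``.  Classes with
    fewer than three distinct years keep raw counts only, with the
    ``smoothed`` column absent (NaN) and ``too_few_years`` flagged.
    """
    if axis not in ("collection_year", "submission_year"):
        raise ValueError(f"unknown axis {axis!r}")
    sub = records[records[axis].notna()].copy()
    sub["contributor_class"] = sub["copyright_country"].map(contributor_class)
    sub = sub[sub["contributor_class"].isin(["Philippines", "Foreign"])]
    frames = []
    for cls, grp in sub.groupby("contributor_class"):
        counts = grp.groupby(axis).size().sort_index()
        years = counts.index.to_numpy(dtype=float)
        values = counts.to_numpy(dtype=float)
        frame = pd.DataFrame(
            {
                "contributor_class": cls,
                "year": years.astype(int),
                "n_records": values.astype(int),
            }
        )
        if len(years) >= 3:
            frame["smoothed"] = loess_smooth(years, values, span=span)
            frame["too_few_years"] = False
        else:
            frame["smoothed"] = float("nan")
            frame["too_few_years"] = True
        frames.append(frame)
    if not frames:
        return pd.DataFrame(
            columns=[
                "contributor_class",
                "year",
                "n_records",
                "smoothed",
                "too_few_years",
            ]
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Region matrix


def assign_regions(
    records: pd.DataFrame,
    gazetteer: Gazetteer,
    institution_map: dict[str, tuple[str, str | None]],
    geometries: ProvinceGeometries | None = None,
) -> pd.DataFrame:
    """Attach sampled region (via province) and processing region (via
    the copyright-holding institution) to each record.

    With geometries supplied, the sampled province uses the coordinate-first
    assignment (spatial join, nearest centroid offshore) consistent with the
    per-province tallies; otherwise the resolved province field is used.
    """
    out = records.copy()
    province_region = {
        p: gazetteer.region_of_province(p) for p in gazetteer.names("province")
    }
    if geometries is not None:
        provinces, _ = effective_provinces(out, geometries)
        province_series = pd.Series(provinces, index=out.index, dtype=object)
    else:
        province_series = out["province"]
    out["sampled_region"] = province_series.map(province_region)
    region_of = {k: v[1] for k, v in institution_map.items()}
    out["processing_region"] = out["copyright_institution"].map(
        lambda i: region_of.get(i) if pd.notna(i) else None
    )
    return out


def region_matrix(
    records: pd.DataFrame, region_order: list[str]
) -> tuple[pd.DataFrame, ResidueLog]:
    """Cross-tabulate processing region x sampled region.

    Restricted to records with both regions known; the row/column ordering
    follows the supplied proximity order.  A region present in the records
    but absent from the order is an error.
    """
    both = records[
        records["processing_region"].notna() & records["sampled_region"].notna()
    ]
    for col in ("processing_region", "sampled_region"):
        unknown = set(both[col]) - set(region_order)
        if unknown:
            raise ValueError(
                f"region(s) {sorted(unknown)} in records but not in region order"
            )
    matrix = pd.crosstab(both["processing_region"], both["sampled_region"])
    matrix = matrix.reindex(
        index=region_order, columns=region_order, fill_value=0
    )
    matrix.index.name = "processing_region"
    matrix.columns.name = "sampled_region"
    residue = ResidueLog(
        {
            "missing_processing_region": int(
                records["processing_region"].isna().sum()
            ),
            "missing_sampled_region": int(
                (
                    records["processing_region"].notna()
                    & records["sampled_region"].isna()
                ).sum()
            ),
        }
    )
    return matrix, residue
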