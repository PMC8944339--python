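"""Province polygon container, GeoJSON I/O and great-circle distance."""

from __future__ import annotations

import json
import math

from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

EARTH_RADIUS_KM = 6371.0088


def haversine_km(
    lat1: float, lon1: float, lat2: float, lon2: float
) -> float:
    """Great-circle distance between two WGS84 points, in kilometres."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlmb = math.radians(lon2 - lon1)
    a = (
        math.sin(dphi / 2) ** 2
        + math.cos(p1) * math.cos(p2) * math.sin(dlmb / 2) ** 2
    )
    return 2 * EARTH_RADIUS_KM * math.asin(math.sqrt(a))


class ProvinceGeometries:
    """Ordered set of named province polygons with cached centroids.

    The iteration order is the fixed province order used to resolve boundary
    points that touch more than one polygon.
    """

    def __init__(self, polygons: dict[str, BaseGeometry]):
        if not polygons:
            raise ValueError("empty geometry set")
        self._polys = dict(polygons)
        # centroid as (lat, lon); area-weighted polygon centroid
        self._centroids = {
            name: (poly.centroid.y, poly.centroid.x)
            for name, poly in self._polys.items()
        }

    @property
    def provinces(self) -> list[str]:
        return list(self._polys)

    def __len__(self) -> int:
        return len(self._polys)

    def __contains__(self, name: str) -> bool:
        return name in self._polys

    def polygon(self, name: str) -> BaseGeometry:
        return self._polys[name]

    def centroid(self, name: str) -> tuple[float, float]:
        """(latitude, longitude) of the province's polygon centroid."""
        return self._centroids[name]

    def items(self):
        return self._polys.items()

    # -- GeoJSON ----------------------------------------------------------

    def to_geojson(self, path) -> None:
        features = [
            {
                "type": "Feature",
                "properties": {"province": name},
                "geometry": mapping(poly),
            }
            for name, poly in self._polys.items()
        ]
        doc = {"type": "FeatureCollection", "features": features}
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_geojson(cls, path) -> "ProvinceGeometries":
        with open(path) as fh:
            doc = json.load(fh)
        polys = {
            feat["properties"]["province"]: shape(feat["geometry"])
            for feat in doc["features"]
        }
        return cls(polys)
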