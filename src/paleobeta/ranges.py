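"""Geographic ranges and bounding regions.

Species ranges are modelled as geodesic disks by default (centre plus an
angular radius), but everything downstream only needs a vectorised
point-in-range test, so polygonal ranges (via shapely) and raster cell-set
ranges (from climate-envelope projections) plug in through the same
interface. All boundaries are closed: a point exactly on the edge counts
as inside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class GeoBounds:
    """A latitude/longitude bounding box (degrees, closed)."""

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float

    def __post_init__(self) -> None:
        if not (-90 <= self.lat_min < self.lat_max <= 90):
            raise ValueError(f"invalid latitude bounds [{self.lat_min}, {self.lat_max}]")
        if not (-180 <= self.lon_min < self.lon_max <= 180):
            raise ValueError(f"invalid longitude bounds [{self.lon_min}, {self.lon_max}]")

    def contains(self, lat, lon) -> np.ndarray:
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        return (
            (lat >= self.lat_min)
            & (lat <= self.lat_max)
            & (lon >= self.lon_min)
            & (lon <= self.lon_max)
        )


def central_angle_deg(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle central angle between points, in degrees (haversine)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return np.degrees(2.0 * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0))))


@runtime_checkable
class Range(Protocol):
    """Anything with a vectorised closed point-in-range test."""

    def contains(self, lat, lon) -> np.ndarray: ...


@dataclass(frozen=True)
class GeodesicDisk:
    """Disk on the sphere: centre plus angular radius in degrees."""

    center_lat: float
    center_lon: float
    radius_deg: float

    def __post_init__(self) -> None:
        if self.radius_deg <= 0:
            raise ValueError("range radius must be positive")

    def contains(self, lat, lon) -> np.ndarray:
        angle = central_angle_deg(lat, lon, self.center_lat, self.center_lon)
        return angle <= self.radius_deg


class PolygonRange:
    """Range defined by a shapely polygon in (lon, lat) coordinates."""

    def __init__(self, polygon) -> None:
        self.polygon = polygon

    def contains(self, lat, lon) -> np.ndarray:
        from shapely.geometry import Point

        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        # covers() (not contains()) keeps boundary points inside
        return np.array([self.polygon.covers(Point(x, y)) for y, x in zip(lat, lon)])


class CellSetRange:
    """Range defined by a set of grid-cell centres (used for projected
    presences on a regular lat/lon grid)."""

    def __init__(self, cell_centers: np.ndarray, resolution_deg: float = 1.0) -> None:
        centers = np.asarray(cell_centers, dtype=float).reshape(-1, 2)
        self.resolution_deg = float(resolution_deg)
        self._cells = {self._key(lat, lon) for lat, lon in centers}

    def _key(self, lat: float, lon: float) -> tuple[int, int]:
        r = self.resolution_deg
        return (int(np.floor(lat / r + 0.5)), int(np.floor(lon / r + 0.5)))

    def contains(self, lat, lon) -> np.ndarray:
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        return np.array([self._key(a, b) in self._cells for a, b in zip(lat, lon)])

    def __len__(self) -> int:
        return len(self._cells)
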