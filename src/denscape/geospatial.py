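"""Planar geometry engine: buffers, uniform disc sampling, point-in-polygon
classification and nearest-feature distances.

All coordinates are planar metric (projected, meters). Geographic
(longitude/latitude) inputs are rejected: distance ratios are meaningless on
an unprojected sphere at this scale.

The land-cover universe is the closed six-class set used throughout the
package, plus a road polyline layer.  ``nearest_distance`` implements the
zero-if-containing rule: a point lying inside (or on the boundary of) a
polygon of the focal class is at distance zero to that class; every other
class is measured to its polygon boundaries.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Point, Polygon, mapping, shape

# Fixed class ordering; also the documented tie-break for boundary points.
LAND_COVER_CLASSES: tuple[str, ...] = (
    "grassland",
    "plantation",
    "agricultural",
    "fallow",
    "ploughed",
    "built_up",
)
ROADS = "roads"
FEATURES: tuple[str, ...] = LAND_COVER_CLASSES + (ROADS,)

SQ_M_PER_HA = 1e4


class GeometryError(ValueError):
    """Invalid geometry or geometry-parameter input."""


@dataclass
class LandscapeMap:
    """Vector land-cover mosaic: one polygon layer per class plus roads.

    Parameters
    ----------
    class_layers
        Mapping from land-cover class (a member of ``LAND_COVER_CLASSES``)
        to a list of shapely Polygons.  Classes may be absent or empty.
    roads
        List of shapely LineStrings.
    crs_note
        Free-text statement of the planar metric CRS.  Anything that looks
        geographic (``"EPSG:4326"``, ``"WGS84"``, degrees) is rejected.
    """

    class_layers: dict[str, list[Polygon]] = field(default_factory=dict)
    roads: list[LineString] = field(default_factory=list)
    crs_note: str = "planar metric (meters)"

    def __post_init__(self) -> None:
        low = self.crs_note.lower()
        if any(tag in low for tag in ("4326", "wgs84", "wgs 84", "degree", "lat/lon", "geographic")):
            raise GeometryError(
                f"geographic coordinates are not supported (crs_note={self.crs_note!r}); "
                "reproject to a planar metric CRS"
            )
        for cls in self.class_layers:
            if cls not in LAND_COVER_CLASSES:
                raise GeometryError(
                    f"unknown land-cover class {cls!r}; expected one of {LAND_COVER_CLASSES}"
                )

    # -- cached prepared geometry ------------------------------------------
    def _union(self, feature: str):
        cache = self.__dict__.setdefault("_union_cache", {})
        if feature not in cache:
            if feature == ROADS:
                geoms = list(self.roads)
            else:
                geoms = list(self.class_layers.get(feature, []))
            if not geoms:
                cache[feature] = None
            else:
                u = shapely.union_all(geoms)
                shapely.prepare(u)
                cache[feature] = u
        return cache[feature]

    def _boundary(self, feature: str):
        """Boundary geometry of a polygon layer (lines), used for distances."""
        cache = self.__dict__.setdefault("_boundary_cache", {})
        if feature not in cache:
            u = self._union(feature)
            cache[feature] = None if u is None else shapely.boundary(u)
        return cache[feature]

    def feature_layers(self) -> dict[str, list]:
        out: dict[str, list] = {c: list(self.class_layers.get(c, [])) for c in LAND_COVER_CLASSES}
        out[ROADS] = list(self.roads)
        return out

    def total_class_area(self) -> float:
        return float(
            sum(p.area for polys in self.class_layers.values() for p in polys)
        )

    def is_empty(self) -> bool:
        return not any(self.class_layers.values()) and not self.roads

    def translate(self, dx: float, dy: float) -> "LandscapeMap":
        import shapely.affinity

        return LandscapeMap(
            class_layers={
                c: [shapely.affinity.translate(p, dx, dy) for p in polys]
                for c, polys in self.class_layers.items()
            },
            roads=[shapely.affinity.translate(r, dx, dy) for r in self.roads],
            crs_note=self.crs_note,
        )


def buffer_area_ha(radius_m: float) -> float:
    """Area of a circular buffer of ``radius_m`` meters, in hectares."""
    if not np.isfinite(radius_m) or radius_m <= 0:
        raise GeometryError(f"buffer radius must be positive, got {radius_m}")
    return math.pi * radius_m**2 / SQ_M_PER_HA


def sample_uniform_disc(
    center: tuple[float, float], radius_m: float, n: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Sample ``n`` points i.i.d. uniform over the disc of radius ``radius_m``.

    Uses the exact areal transform r = R*sqrt(u), theta uniform on [0, 2pi).
    Returns an (n, 2) array of x, y coordinates.
    """
    if n < 0:
        raise GeometryError(f"number of points must be >= 0, got {n}")
    if radius_m <= 0:
        raise GeometryError(f"disc radius must be positive, got {radius_m}")
    rng = np.random.default_rng(seed)
    r = radius_m * np.sqrt(rng.random(n))
    theta = rng.random(n) * 2 * math.pi
    cx, cy = float(center[0]), float(center[1])
    return np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])


def land_cover_at(point: tuple[float, float], landscape: LandscapeMap) -> str | None:
    """Land-cover class containing the point, or None if uncovered.

    Boundary points count as inside; a point on a shared boundary is assigned
    to the class listed first in ``LAND_COVER_CLASSES`` (documented tie-break).
    """
    p = Point(point)
    for cls in LAND_COVER_CLASSES:
        u = landscape._union(cls)
        if u is not None and shapely.covers(u, p):
            return cls
    return None


def nearest_distance(point, landscape: LandscapeMap, feature: str) -> float:
    """Nearest Euclidean distance (m) from a point to a feature layer.

    Zero if the point lies inside or on a polygon of that class; otherwise
    the minimum distance to the layer's boundary lines (for roads, to any
    polyline).  Raises if the feature layer is empty.
    """
    return float(nearest_distances(np.asarray(point, float)[None, :], landscape, feature)[0])


def nearest_distances(points: np.ndarray, landscape: LandscapeMap, feature: str) -> np.ndarray:
    """Vectorized ``nearest_distance`` over an (n, 2) array of points."""
    if feature not in FEATURES:
        raise GeometryError(f"unknown feature {feature!r}; expected one of {FEATURES}")
    u = landscape._union(feature)
    if u is None:
        raise GeometryError(f"feature layer {feature!r} is empty")
    pts = shapely.points(np.asarray(points, dtype=float))
    if feature == ROADS:
        return shapely.distance(pts, u)
    d = shapely.distance(pts, shapely.boundary(u))
    inside = shapely.covers(u, pts)
    d[inside] = 0.0
    return d


# ---------------------------------------------------------------------------
# I/O: GeoJSON landscapes, CSV point tables
# ---------------------------------------------------------------------------

def write_landscape(landscape: LandscapeMap, path: str) -> None:
    """Write a landscape as a GeoJSON FeatureCollection.

    Each polygon carries a ``layer`` property naming its land-cover class;
    roads carry ``layer: "roads"``.
    """
    feats = []
    for cls, polys in landscape.class_layers.items():
        for p in polys:
            feats.append({"type": "Feature", "properties": {"layer": cls}, "geometry": mapping(p)})
    for r in landscape.roads:
        feats.append({"type": "Feature", "properties": {"layer": ROADS}, "geometry": mapping(r)})
    doc = {
        "type": "FeatureCollection",
        "crs_note": landscape.crs_note,
        "features": feats,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_landscape(path: str) -> LandscapeMap:
    """Read a landscape written by :func:`write_landscape`."""
    with open(path) as fh:
        doc = json.load(fh)
    layers: dict[str, list[Polygon]] = {}
    roads: list[LineString] = []
    for feat in doc["features"]:
        layer = feat["properties"]["layer"]
        geom = shape(feat["geometry"])
        if layer == ROADS:
            roads.append(geom)
        else:
            layers.setdefault(layer, []).append(geom)
    return LandscapeMap(
        class_layers=layers, roads=roads, crs_note=doc.get("crs_note", "planar metric (meters)")
    )


def read_points_csv(path: str) -> np.ndarray:
    """Read an (n, 2) point array from a CSV with x, y columns."""
    df = pd.read_csv(path)
    if not {"x", "y"}.issubset(df.columns):
        raise GeometryError(f"point CSV {path!r} must have 'x' and 'y' columns")
    return df[["x", "y"]].to_numpy(dtype=float)
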