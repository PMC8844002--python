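"""Sun-shade composition of path options from 2.5D scene geometry.

A scene is a set of extruded building footprints and ellipsoidal tree crowns
in a local metric east-north-up frame, plus the walking-path strips.  For a
given sun position, every strip is sampled on a 0.1 m grid and one ray is
shot from each grid point toward the sun:

* a ray that enters a building's vertical extrusion counts as building shade
  (buildings take precedence: they block light completely);
* otherwise a ray that pierces a tree-crown ellipsoid counts as tree shade;
* otherwise the point is in the sun.

Of the parallel strips of a wide path, the one with the lowest sun fraction
is taken as representative of the whole path, and building shade covering
less than 15% of a wide path is treated as absent (too thin a sliver to be
registered by a walker).  Fractions times the option's centreline length give
the metric sun/tree-shade/building-shade decomposition.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from shapely.geometry import Polygon, mapping, shape

from .choice import PathComposition
from .solar import SunPosition

__all__ = [
    "Building",
    "TreeCrown",
    "PathOption",
    "Scene",
    "ShadeFractions",
    "cast_fractions",
    "representative_composition",
    "apply_min_building_shade_rule",
    "compose_lengths",
    "composition_for_option",
    "scene_from_geojson",
    "scene_to_geojson",
]

#: Grid pitch (m) of the ray lattice and the building-shade significance
#: threshold for wide paths.
DEFAULT_GRID_STEP = 0.1
MIN_BUILDING_SHADE_FRACTION = 0.15
#: Wide paths are represented by 5 parallel strips of 1.2 m each.
WIDE_PATH_STRIPS = 5
WIDE_STRIP_WIDTH = 1.2


@dataclass(frozen=True)
class ShadeFractions:
    """Fractions of a strip in the sun, tree shade and building shade (sum to 1)."""

    f_sun: float
    f_tree: float
    f_building: float

    def __post_init__(self) -> None:
        for name in ("f_sun", "f_tree", "f_building"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")
        if abs(self.f_sun + self.f_tree + self.f_building - 1.0) > 1e-9:
            raise ValueError(
                f"fractions must sum to 1, got {self.f_sun + self.f_tree + self.f_building!r}"
            )


@dataclass(frozen=True)
class Building:
    """A building as a footprint polygon extruded vertically to ``height``."""

    footprint: Polygon
    height: float

    def __post_init__(self) -> None:
        if not self.height > 0:
            raise ValueError(f"building height must be > 0, got {self.height!r}")
        if self.footprint.is_empty or not self.footprint.is_valid or self.footprint.area <= 0:
            raise ValueError("building footprint must be a valid non-degenerate polygon")


@dataclass(frozen=True)
class TreeCrown:
    """A tree crown modelled as an axis-aligned ellipsoid (the crown's convex hull).

    ``center`` is the crown centre (x, y, z) in metres; ``semi_axes`` the
    ellipsoid semi-axes (sx, sy, sz) in metres.
    """

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def __post_init__(self) -> None:
        if any(not s > 0 for s in self.semi_axes):
            raise ValueError(f"crown semi-axes must be > 0, got {self.semi_axes!r}")


@dataclass(frozen=True)
class PathOption:
    """One path option: an ordered sequence of strip polygons plus metadata."""

    option_id: str
    strips: tuple[Polygon, ...]
    length: float
    is_wide: bool = False
    strip_width: float = WIDE_STRIP_WIDTH

    def __post_init__(self) -> None:
        if len(self.strips) == 0:
            raise ValueError(f"path option {self.option_id!r} has no strips")
        for i, s in enumerate(self.strips):
            if s.is_empty or not s.is_valid or s.area <= 0:
                raise ValueError(f"strip {i} of option {self.option_id!r} is degenerate")
        if not self.length > 0:
            raise ValueError(f"option {self.option_id!r} length must be > 0")


@dataclass(frozen=True)
class Scene:
    """2.5D scene: site coordinates, buildings, tree crowns and path options."""

    site_latitude: float
    site_longitude: float
    buildings: tuple[Building, ...] = ()
    trees: tuple[TreeCrown, ...] = ()
    path_options: dict[str, PathOption] = field(default_factory=dict)


def _grid_points(strip: Polygon, grid_step: float) -> np.ndarray:
    """Cell centres of an axis-aligned ``grid_step`` lattice inside the strip.

    The lattice is anchored at the global origin (centres at (i + 1/2) * step)
    so results do not depend on the strip's bounding box, making repeated
    calls bit-identical.
    """
    minx, miny, maxx, maxy = strip.bounds
    i0 = math.floor(minx / grid_step)
    i1 = math.ceil(maxx / grid_step)
    j0 = math.floor(miny / grid_step)
    j1 = math.ceil(maxy / grid_step)
    xs = (np.arange(i0, i1) + 0.5) * grid_step
    ys = (np.arange(j0, j1) + 0.5) * grid_step
    xx, yy = np.meshgrid(xs, ys)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    inside = shapely.contains_xy(strip, pts[:, 0], pts[:, 1])
    return pts[inside]


def _building_hits(pts: np.ndarray, sun: SunPosition, building: Building) -> np.ndarray:
    """Boolean mask of ground points whose sun-ray enters the building extrusion.

    A ray from ground level reaches height z after a horizontal run of
    z / tan(elevation) toward the sun's azimuth, so the ray is blocked iff the
    horizontal segment from the point to its position at the roof height
    intersects the footprint.
    """
    dx, dy, dz = sun.direction
    run = building.height / dz  # parameter at which the ray tops the building
    ends = pts + np.array([dx, dy]) * run
    coords = np.stack([pts, ends], axis=1)  # (n, 2, 2)
    segments = shapely.linestrings(coords)
    return shapely.intersects(segments, building.footprint)


def _tree_hits(pts: np.ndarray, sun: SunPosition, tree: TreeCrown) -> np.ndarray:
    """Boolean mask of points whose sun-ray pierces the crown ellipsoid."""
    d = np.array(sun.direction)
    c = np.array(tree.center)
    s = np.array(tree.semi_axes)
    o = np.column_stack([pts[:, 0], pts[:, 1], np.zeros(len(pts))]) - c
    ds = d / s
    os = o / s
    a = float(ds @ ds)
    b = 2.0 * os @ ds
    cc = np.einsum("ij,ij->i", os, os) - 1.0
    disc = b * b - 4.0 * a * cc
    hit = disc >= 0.0
    # require an intersection at positive ray parameter (toward the sun)
    sq = np.sqrt(np.maximum(disc, 0.0))
    t_hi = (-b + sq) / (2.0 * a)
    return hit & (t_hi > 0.0)


def cast_fractions(
    scene: Scene,
    strip: Polygon,
    sun: SunPosition,
    grid_step: float = DEFAULT_GRID_STEP,
) -> ShadeFractions:
    """Ray-cast one strip polygon against the scene for a given sun position.

    Shoots one ray toward the sun from every lattice point inside the strip
    and returns the hit-count fractions.  Building occlusion takes precedence
    over tree occlusion.
    """
    if sun.elevation <= 0.0:
        raise ValueError(
            f"sun is at or below the horizon (elevation {sun.elevation:.2f} deg); "
            "shading is undefined at night"
        )
    if not grid_step > 0:
        raise ValueError(f"grid_step must be > 0, got {grid_step!r}")
    pts = _grid_points(strip, grid_step)
    n = len(pts)
    if n == 0:
        raise ValueError(
            f"strip with bounds {strip.bounds} contains no grid points at step {grid_step}"
        )
    in_building = np.zeros(n, dtype=bool)
    for b in scene.buildings:
        in_building |= _building_hits(pts, sun, b)
    in_tree = np.zeros(n, dtype=bool)
    for t in scene.trees:
        in_tree |= _tree_hits(pts, sun, t)
    in_tree &= ~in_building
    f_building = in_building.sum() / n
    f_tree = in_tree.sum() / n
    f_sun = 1.0 - f_building - f_tree
    return ShadeFractions(f_sun=f_sun, f_tree=f_tree, f_building=f_building)


def representative_composition(fractions_per_strip: list[ShadeFractions]) -> ShadeFractions:
    """The strip with the lowest sun fraction represents the whole path.

    Ties are broken toward the lowest strip index.
    """
    if len(fractions_per_strip) == 0:
        raise ValueError("fractions_per_strip is empty")
    idx = int(np.argmin([f.f_sun for f in fractions_per_strip]))
    return fractions_per_strip[idx]


def apply_min_building_shade_rule(
    fractions: ShadeFractions,
    path_is_wide: bool,
    threshold: float = MIN_BUILDING_SHADE_FRACTION,
) -> ShadeFractions:
    """Discard insufficient building shade on wide paths.

    Building shade covering strictly less than ``threshold`` (default 15%,
    i.e. under 0.9 m of a 6 m path) of a wide path is too thin to give
    walkable relief; its mass is reassigned to sun.  Narrow paths are
    returned unchanged.
    """
    if path_is_wide and fractions.f_building < threshold:
        return ShadeFractions(
            f_sun=fractions.f_sun + fractions.f_building,
            f_tree=fractions.f_tree,
            f_building=0.0,
        )
    return fractions


def compose_lengths(option_length: float, fractions: ShadeFractions) -> PathComposition:
    """Metric decomposition: each component is the option length times its fraction."""
    if not option_length > 0:
        raise ValueError(f"option_length must be > 0, got {option_length!r}")
    return PathComposition(
        a_sun=option_length * fractions.f_sun,
        a_tree=option_length * fractions.f_tree,
        a_shade=option_length * fractions.f_building,
    )


def composition_for_option(
    scene: Scene,
    option_id: str,
    sun: SunPosition,
    grid_step: float = DEFAULT_GRID_STEP,
) -> PathComposition:
    """Full per-option pipeline: cast every strip, pick the representative one,
    apply the wide-path minimum-building-shade rule, convert to metres."""
    option = scene.path_options[option_id]
    per_strip = [cast_fractions(scene, s, sun, grid_step) for s in option.strips]
    rep = representative_composition(per_strip)
    rep = apply_min_building_shade_rule(rep, option.is_wide)
    return compose_lengths(option.length, rep)


# ---------------------------------------------------------------------------
# GeoJSON scene files (local metric CRS)

def scene_from_geojson(source: str | Path | dict) -> Scene:
    """Load a scene from a GeoJSON FeatureCollection in a local metric frame.

    Buildings: Polygon features with property ``height_m``.  Trees: Point
    features with ``crown_cx_m`` (horizontal semi-axis), ``crown_cz_m``
    (vertical semi-axis) and ``crown_base_m`` (crown base height).  Path
    strips: Polygon features with ``option_id``, ``strip_index``, ``is_wide``
    and ``length_m``.  Site coordinates live in top-level ``properties``.
    """
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            data = json.load(fh)
    else:
        data = source
    props = data.get("properties", {})
    lat = float(props.get("site_latitude", 0.0))
    lon = float(props.get("site_longitude", 0.0))
    buildings: list[Building] = []
    trees: list[TreeCrown] = []
    strips: dict[str, list[tuple[int, Polygon]]] = {}
    meta: dict[str, dict] = {}
    for feat in data["features"]:
        fprops = feat.get("properties", {})
        geom = shape(feat["geometry"])
        if "height_m" in fprops:
            buildings.append(Building(footprint=geom, height=float(fprops["height_m"])))
        elif "crown_cx_m" in fprops:
            cx = float(fprops["crown_cx_m"])
            cz = float(fprops["crown_cz_m"])
            base = float(fprops["crown_base_m"])
            trees.append(
                TreeCrown(
                    center=(geom.x, geom.y, base + cz),
                    semi_axes=(cx, cx, cz),
                )
            )
        elif "option_id" in fprops:
            oid = str(fprops["option_id"])
            strips.setdefault(oid, []).append((int(fprops.get("strip_index", 0)), geom))
            meta[oid] = {
                "is_wide": bool(fprops.get("is_wide", False)),
                "length": float(fprops["length_m"]),
            }
        else:
            raise ValueError(f"unrecognised feature properties: {sorted(fprops)}")
    options = {
        oid: PathOption(
            option_id=oid,
            strips=tuple(p for _, p in sorted(lst, key=lambda t: t[0])),
            length=meta[oid]["length"],
            is_wide=meta[oid]["is_wide"],
        )
        for oid, lst in strips.items()
    }
    return Scene(
        site_latitude=lat,
        site_longitude=lon,
        buildings=tuple(buildings),
        trees=tuple(trees),
        path_options=options,
    )


def scene_to_geojson(scene: Scene, path: str | Path | None = None) -> dict:
    """Serialise a scene to the GeoJSON layout accepted by ``scene_from_geojson``."""
    features: list[dict] = []
    for b in scene.buildings:
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(b.footprint),
                "properties": {"height_m": b.height},
            }
        )
    for t in scene.trees:
        cx, cy, cz_center = t.center
        sx, _, sz = t.semi_axes
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [cx, cy]},
                "properties": {
                    "crown_cx_m": sx,
                    "crown_cz_m": sz,
                    "crown_base_m": cz_center - sz,
                },
            }
        )
    for oid, opt in scene.path_options.items():
        for i, strip in enumerate(opt.strips):
            features.append(
                {
                    "type": "Feature",
                    "geometry": mapping(strip),
                    "properties": {
                        "option_id": oid,
                        "strip_index": i,
                        "is_wide": opt.is_wide,
                        "length_m": opt.length,
                    },
                }
            )
    doc = {
        "type": "FeatureCollection",
        "properties": {
            "site_latitude": scene.site_latitude,
            "site_longitude": scene.site_longitude,
        },
        "features": features,
    }
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh)
    return doc
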