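"""Geometry preprocessing: from raw PA and land/country polygon layers to
the abstract node/distance inputs of the dispersal network.

The pipeline mirrors the standard global PA workflow:

1. filter sites (drop proposed / not-reported status, point sites without
   a reported area, UNESCO Man and the Biosphere reserves);
2. buffer retained point sites to circles matching their reported area;
3. dissolve overlapping designations (no double counting) and simplify;
4. clip to the land mask, explode multiparts, drop parts below the minimum
   area threshold (1 km² default), assign country codes (multi-country
   sites are split along country boundaries);
5. label each node with its land portion (connected component of one
   country's land) and landmass (connected component of all land);
6. select transboundary candidates within a 500 km buffer of the focal
   country's PAs;
7. compute pairwise edge-to-edge distances.

All coordinates are planar kilometres (synthetic worlds are generated on a
flat plane), so areas and distances come straight from the geometry; no
geodesic projection step is involved.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

from shapely.geometry.base import BaseGeometry
from shapely.geometry import Point, Polygon, MultiPolygon
from shapely.ops import unary_union
from shapely.validation import make_valid
from shapely import STRtree

from .network import PANode, pair_key

__all__ = [
    "RawPASite",
    "LandFeature",
    "PANodeGeom",
    "PreprocessConfig",
    "filter_sites",
    "buffer_point_site",
    "dissolve_and_simplify",
    "clip_explode_filter",
    "label_portions_landmasses",
    "select_transboundary",
    "pairwise_edge_distances",
    "country_land_area",
    "preprocess_country",
]

logger = logging.getLogger(__name__)

#: site status values removed from the analysis (case-insensitive)
EXCLUDED_STATUS = {"proposed", "not reported"}
KNOWN_STATUS = EXCLUDED_STATUS | {"designated", "inscribed", "adopted", "established"}


@dataclass(frozen=True)
class RawPASite:
    """One protected-area record as reported in a WDPA-like inventory.

    ``iso3`` may list several countries separated by ``;`` (e.g. a World
    Heritage Site spanning a border); such sites are split along country
    boundaries downstream.  Point sites must carry ``reported_area_km2``
    to be retained.
    """

    site_id: str
    geometry: BaseGeometry
    iso3: str
    status: str = "Designated"
    designation_type: str = ""
    reported_area_km2: float | None = None
    iucn_category: str | None = None


@dataclass(frozen=True)
class LandFeature:
    """One country-territory polygon of the land/boundary layer."""

    geometry: BaseGeometry
    iso3: str
    disputed: bool = False


@dataclass
class PANodeGeom:
    """A dissolved terrestrial PA polygon with its network labels."""

    node_id: str
    iso3: str
    geometry: BaseGeometry
    area_km2: float
    portion_id: str | None = None
    landmass_id: str | None = None
    is_transboundary: bool = False

    def to_pa_node(self) -> PANode:
        if self.portion_id is None or self.landmass_id is None:
            raise ValueError(f"node {self.node_id} not yet labelled")
        return PANode(
            node_id=self.node_id,
            area=self.area_km2,
            iso3=self.iso3,
            portion_id=self.portion_id,
            landmass_id=self.landmass_id,
            is_transboundary=self.is_transboundary,
        )


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunable preprocessing parameters (defaults are the standard ones)."""

    min_area_km2: float = 1.0
    simplify_km: float = 0.1          # 100 m vertex simplification
    buffer_km: float = 500.0          # transboundary search radius
    contiguity_tol_km: float = 0.0    # boundary distance treated as contiguous


# ---------------------------------------------------------------------------
# site filtering and point buffering


def filter_sites(sites: list[RawPASite]) -> list[RawPASite]:
    """Apply the inventory inclusion rules.

    Drops sites with proposed / not-reported status, point sites without a
    positive reported area, and UNESCO Man and the Biosphere reserves.
    Sites with a missing IUCN category are kept.  Unknown status strings
    are retained with a warning rather than failing the run.
    """
    kept: list[RawPASite] = []
    for s in sites:
        status = s.status.strip().lower()
        if status in EXCLUDED_STATUS:
            logger.info("dropped %s: status %r", s.site_id, s.status)
            continue
        if status not in KNOWN_STATUS:
            logger.warning("unknown status %r on %s: retained", s.status, s.site_id)
        if "man and the biosphere" in s.designation_type.lower() or \
                "mab" == s.designation_type.strip().lower():
            logger.info("dropped %s: UNESCO MAB reserve", s.site_id)
            continue
        if isinstance(s.geometry, Point) and not (
            s.reported_area_km2 and s.reported_area_km2 > 0
        ):
            logger.info("dropped %s: point without reported area", s.site_id)
            continue
        kept.append(s)
    return kept


def buffer_point_site(site: RawPASite, quad_segs: int = 256) -> Polygon:
    """Circular buffer around a point site with area equal to the reported
    one (within 0.1%); radius r = sqrt(A / pi) in planar km."""
    if not isinstance(site.geometry, Point):
        raise TypeError(f"{site.site_id} is not a point site")
    if not site.reported_area_km2 or site.reported_area_km2 <= 0:
        raise ValueError(f"{site.site_id} has no positive reported area")
    radius = math.sqrt(site.reported_area_km2 / math.pi)
    return site.geometry.buffer(radius, quad_segs=quad_segs)


# ---------------------------------------------------------------------------
# dissolve / clip / explode


def _as_polygons(geom: BaseGeometry) -> list[Polygon]:
    """Explode any geometry into its polygonal parts (drop slivers of other
    dimensions produced by clipping)."""
    if geom.is_empty:
        return []
    if isinstance(geom, Polygon):
        return [geom]
    if isinstance(geom, MultiPolygon):
        return list(geom.geoms)
    if hasattr(geom, "geoms"):  # GeometryCollection
        out: list[Polygon] = []
        for g in geom.geoms:
            out.extend(_as_polygons(g))
        return out
    return []


def _repair(geom: BaseGeometry, ident: str) -> BaseGeometry | None:
    if geom.is_valid:
        return geom
    fixed = make_valid(geom)
    if fixed.is_empty:
        logger.warning("dropped %s: unrepairable geometry", ident)
        return None
    logger.info("repaired invalid geometry on %s", ident)
    return fixed


def dissolve_and_simplify(
    polygons: list[BaseGeometry], simplify_km: float = 0.1
) -> list[Polygon]:
    """Dissolve overlapping designations into non-overlapping polygons and
    reduce vertex counts with a topology-preserving simplification.

    Dissolving first guarantees no double counting of area; the dissolved
    area never exceeds the union of the inputs.
    """
    repaired = []
    for i, g in enumerate(polygons):
        fixed = _repair(g, f"polygon[{i}]")
        if fixed is not None:
            repaired.append(fixed)
    if not repaired:
        return []
    merged = unary_union(repaired)
    out = []
    for part in _as_polygons(merged):
        simplified = part.simplify(simplify_km, preserve_topology=True)
        if not simplified.is_empty and simplified.area > 0:
            out.extend(_as_polygons(simplified))
    return out


def clip_explode_filter(
    pa_polygons: list[tuple[str, BaseGeometry]],
    land: list[LandFeature],
    min_area_km2: float = 1.0,
) -> list[PANodeGeom]:
    """Clip PA polygons to land, explode multiparts, drop small parts.

    ``pa_polygons`` carries (iso3, geometry) pairs; multi-country entries
    (iso3 with ``;``) are split by intersection with the country
    boundaries first.  Parts smaller than ``min_area_km2`` after clipping
    are removed; a PA entirely at sea is dropped (logged).
    """
    land_union = unary_union([f.geometry for f in land])
    by_iso: dict[str, BaseGeometry] = {}
    for f in land:
        by_iso[f.iso3] = unary_union(
            [by_iso[f.iso3], f.geometry]
        ) if f.iso3 in by_iso else f.geometry

    split: list[tuple[str, BaseGeometry]] = []
    for iso3, geom in pa_polygons:
        codes = [c.strip() for c in iso3.split(";") if c.strip()]
        if len(codes) <= 1:
            split.append((iso3, geom))
            continue
        for code in codes:
            if code not in by_iso:
                logger.warning("no land for %s; skipping its share", code)
                continue
            piece = geom.intersection(by_iso[code])
            if not piece.is_empty:
                split.append((code, piece))

    nodes: list[PANodeGeom] = []
    counter = 0
    for iso3, geom in split:
        clipped = geom.intersection(land_union)
        parts = _as_polygons(clipped)
        if not parts:
            logger.info("PA of %s entirely at sea: dropped", iso3)
            continue
        for part in sorted(parts, key=lambda p: (p.bounds, p.area)):
            if part.area < min_area_km2:
                continue
            nodes.append(
                PANodeGeom(
                    node_id=f"{iso3}_{counter:04d}",
                    iso3=iso3,
                    geometry=part,
                    area_km2=part.area,
                )
            )
            counter += 1
    return nodes


# ---------------------------------------------------------------------------
# portion / landmass labelling


def _component_polygons(geoms: list[BaseGeometry]) -> list[Polygon]:
    """Disjoint polygons of the union, deterministically ordered."""
    merged = unary_union(geoms)
    return sorted(_as_polygons(merged), key=lambda p: (p.bounds[0], p.bounds[1]))


def label_portions_landmasses(
    nodes: list[PANodeGeom], land: list[LandFeature]
) -> list[PANodeGeom]:
    """Assign every node its landmass and country-portion labels.

    A landmass is a connected component of all land; a portion is a
    connected component of one country's land (so two portions of the same
    country differ when separated by sea or by foreign territory).  A node
    takes the labels of the portion holding the majority of its area; ties
    break lexicographically for determinism.
    """
    landmasses = _component_polygons([f.geometry for f in land])
    lm_tree = STRtree(landmasses)

    def landmass_of(geom: BaseGeometry) -> str:
        cand = lm_tree.query(geom)
        best, best_area = None, -1.0
        for idx in sorted(cand):
            inter = landmasses[idx].intersection(geom).area
            if inter > best_area:
                best, best_area = idx, inter
        if best is None or best_area <= 0:
            raise ValueError("geometry lies on no landmass")
        return f"L{best}"

    portions_by_iso: dict[str, list[Polygon]] = {}
    for iso3 in sorted({n.iso3 for n in nodes}):
        country_land = [f.geometry for f in land if f.iso3 == iso3]
        if not country_land:
            raise ValueError(f"no land polygons for country {iso3}")
        portions_by_iso[iso3] = _component_polygons(country_land)

    out: list[PANodeGeom] = []
    for n in nodes:
        portions = portions_by_iso[n.iso3]
        best, best_area = None, 0.0
        for idx, poly in enumerate(portions):
            inter = poly.intersection(n.geometry).area
            if inter > best_area:
                best, best_area = idx, inter
        if best is None:
            raise ValueError(
                f"node {n.node_id} does not overlap any land of {n.iso3}"
            )
        portion_poly = portions[best]
        out.append(
            replace(
                n,
                portion_id=f"{n.iso3}/P{best}",
                landmass_id=landmass_of(portion_poly),
            )
        )
    return out


# ---------------------------------------------------------------------------
# transboundary selection and distances


def select_transboundary(
    nodes: list[PANodeGeom], focal_iso3: str, buffer_km: float = 500.0
) -> list[PANodeGeom]:
    """Keep focal-country nodes plus foreign nodes within ``buffer_km`` of
    them (flagged transboundary); foreign nodes further away are dropped.

    A country with zero nodes yields an empty list (a valid empty network,
    not an error).
    """
    focal = [n for n in nodes if n.iso3 == focal_iso3]
    if not focal:
        return []
    buffered = unary_union([n.geometry for n in focal]).buffer(buffer_km)
    out = [replace(n, is_transboundary=False) for n in focal]
    for n in nodes:
        if n.iso3 == focal_iso3:
            continue
        if n.geometry.intersects(buffered):
            out.append(replace(n, is_transboundary=True))
    return sorted(out, key=lambda n: n.node_id)


def pairwise_edge_distances(
    nodes: list[PANodeGeom],
) -> dict[tuple[str, str], float]:
    """Symmetric edge-to-edge (boundary) distances in km; 0 for touching or
    overlapping polygons."""
    dist: dict[tuple[str, str], float] = {}
    for i, a in enumerate(nodes):
        for b in nodes[i + 1:]:
            dist[pair_key(a.node_id, b.node_id)] = a.geometry.distance(b.geometry)
    return dist


def country_land_area(land: list[LandFeature], iso3: str) -> float:
    """Country land area A_L in km², disputed territories excluded."""
    geoms = [f.geometry for f in land if f.iso3 == iso3 and not f.disputed]
    if not geoms:
        raise ValueError(f"no undisputed land for {iso3}")
    return unary_union(geoms).area


# ---------------------------------------------------------------------------
# one-call pipeline


def preprocess_country(
    sites: list[RawPASite],
    land: list[LandFeature],
    focal_iso3: str,
    config: PreprocessConfig = PreprocessConfig(),
) -> tuple[list[PANodeGeom], dict[tuple[str, str], float]]:
    """Run the full preprocessing chain for one focal country.

    Returns the labelled node list (focal + transboundary) and the
    pairwise edge-to-edge distance table.
    """
    kept = filter_sites(sites)
    polygons: list[tuple[str, BaseGeometry]] = []
    for s in kept:
        geom = buffer_point_site(s) if isinstance(s.geometry, Point) else s.geometry
        polygons.append((s.iso3, geom))

    by_iso: dict[str, list[BaseGeometry]] = {}
    for iso3, geom in polygons:
        by_iso.setdefault(iso3, []).append(geom)
    dissolved: list[tuple[str, BaseGeometry]] = []
    for iso3 in sorted(by_iso):
        for poly in dissolve_and_simplify(by_iso[iso3], config.simplify_km):
            dissolved.append((iso3, poly))

    nodes = clip_explode_filter(dissolved, land, config.min_area_km2)
    nodes = label_portions_landmasses(nodes, land)
    nodes = select_transboundary(nodes, focal_iso3, config.buffer_km)
    distances = pairwise_edge_distances(nodes)
    return nodes, distances
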