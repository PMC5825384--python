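"""Geometry preprocessing: filtering, buffering, dissolve, clip/explode,
portion/landmass labelling, transboundary selection, edge distances."""

import math

import numpy as np
import pytest
from shapely.geometry import Point, Polygon, box

from protconn.geometry import (
    LandFeature,
    PreprocessConfig,
    RawPASite,
    buffer_point_site,
    clip_explode_filter,
    country_land_area,
    dissolve_and_simplify,
    filter_sites,
    label_portions_landmasses,
    pairwise_edge_distances,
    preprocess_country,
    select_transboundary,
)
from protconn.network import pair_key


def site(site_id="S1", geometry=None, iso3="AAA", **kw):
    return RawPASite(site_id, geometry or box(0, 0, 10, 10), iso3, **kw)


# ---------------------------------------------------------------------------
# site filtering


@pytest.mark.parametrize(
    "kwargs,kept",
    [
        ({"status": "Proposed"}, False),
        ({"status": "Not Reported"}, False),
        ({"status": "Designated"}, True),
        ({"status": "Designated", "iucn_category": None}, True),  # missing IUCN ok
        ({"designation_type": "UNESCO Man and the Biosphere Reserve"}, False),
        ({"geometry": Point(5, 5), "reported_area_km2": None}, False),
        ({"geometry": Point(5, 5), "reported_area_km2": 10.0}, True),
    ],
)
def test_filter_rules(kwargs, kept):
    result = filter_sites([site(**kwargs)])
    assert bool(result) is kept


def test_unknown_status_retained_with_warning(caplog):
    import logging

    with caplog.at_level(logging.WARNING):
        result = filter_sites([site(status="Whatever")])
    assert len(result) == 1
    assert any("unknown status" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# point buffering


def test_point_buffer_area_matches_reported():
    s = site(geometry=Point(0, 0), reported_area_km2=10.0)
    poly = buffer_point_site(s)
    assert poly.area == pytest.approx(10.0, rel=1e-3)
    # radius of the equivalent circle
    assert poly.bounds[2] == pytest.approx(math.sqrt(10 / math.pi), rel=1e-3)


def test_small_buffered_point_removed_by_area_filter():
    # a 0.5 km² point site yields a polygon that the 1 km² threshold drops
    s = site(geometry=Point(50, 50), reported_area_km2=0.5)
    poly = buffer_point_site(s)
    land = [LandFeature(box(0, 0, 100, 100), "AAA")]
    assert clip_explode_filter([("AAA", poly)], land, min_area_km2=1.0) == []


# ---------------------------------------------------------------------------
# dissolve / simplify


def test_dissolve_removes_double_counting():
    # identical overlapping designations of one 50 km² site -> one polygon
    a = box(0, 0, 10, 5)
    b = box(0, 0, 10, 5)
    out = dissolve_and_simplify([a, b])
    assert len(out) == 1
    assert out[0].area == pytest.approx(50.0)


def test_dissolve_identity_on_disjoint_input():
    a, b = box(0, 0, 10, 10), box(20, 0, 30, 10)
    out = dissolve_and_simplify([a, b])
    assert sorted(p.area for p in out) == pytest.approx([100.0, 100.0])


def test_simplify_preserves_area_of_dense_ring():
    # a 1,000-vertex circle; 100 m tolerance changes the area < 1%
    theta = np.linspace(0, 2 * math.pi, 1001)[:-1]
    ring = Polygon(zip(50 + 30 * np.cos(theta), 50 + 30 * np.sin(theta)))
    out = dissolve_and_simplify([ring], simplify_km=0.1)
    assert len(out) == 1
    assert out[0].area == pytest.approx(ring.area, rel=0.01)
    assert len(out[0].exterior.coords) < len(ring.exterior.coords)


def test_dissolved_area_never_exceeds_union():
    polys = [box(i, 0, i + 5, 5) for i in range(0, 20, 3)]  # overlapping strip
    from shapely.ops import unary_union

    union_area = unary_union(polys).area
    assert sum(p.area for p in dissolve_and_simplify(polys)) <= union_area + 1e-6


# ---------------------------------------------------------------------------
# clip / explode / filter


def test_coastal_pa_clipped_to_land_half():
    land = [LandFeature(box(0, 0, 50, 100), "AAA")]
    pa = box(40, 40, 60, 60)  # half on land, half at sea
    nodes = clip_explode_filter([("AAA", pa)], land)
    assert len(nodes) == 1
    assert nodes[0].area_km2 == pytest.approx(200.0)


def test_multipart_small_piece_dropped():
    land = [LandFeature(box(0, 0, 100, 100), "AAA")]
    from shapely.geometry import MultiPolygon

    mp = MultiPolygon([box(0, 0, 3, 1), box(10, 10, 10.632, 10.632)])  # 3 + 0.4 km²
    nodes = clip_explode_filter([("AAA", mp)], land)
    assert len(nodes) == 1
    assert nodes[0].area_km2 == pytest.approx(3.0)


def test_multi_iso3_site_split_by_boundary():
    land = [LandFeature(box(0, 0, 50, 100), "AAA"),
            LandFeature(box(50, 0, 100, 100), "BBB")]
    pa = box(40, 0, 70, 10)  # straddles the border: 10x10 in AAA, 20x10 in BBB
    nodes = clip_explode_filter([("AAA;BBB", pa)], land)
    by_iso = {n.iso3: n.area_km2 for n in nodes}
    assert by_iso == {"AAA": pytest.approx(100.0), "BBB": pytest.approx(200.0)}


def test_pa_entirely_at_sea_dropped():
    land = [LandFeature(box(0, 0, 50, 50), "AAA")]
    assert clip_explode_filter([("AAA", box(100, 100, 110, 110))], land) == []


# ---------------------------------------------------------------------------
# portion / landmass labelling


def _labelled_nodes(land, pa_boxes, iso3="AAA"):
    nodes = clip_explode_filter([(iso3, b) for b in pa_boxes], land)
    return label_portions_landmasses(nodes, land)


def test_two_islands_two_portions_two_landmasses():
    land = [LandFeature(box(0, 0, 100, 100), "AAA"),
            LandFeature(box(200, 0, 300, 100), "AAA")]
    nodes = _labelled_nodes(land, [box(10, 10, 20, 20), box(210, 10, 220, 20)])
    assert len({n.portion_id for n in nodes}) == 2
    assert len({n.landmass_id for n in nodes}) == 2


def test_enclave_two_portions_one_landmass():
    # country in two pieces on one landmass (an Alaska-like separation)
    land = [LandFeature(box(0, 0, 100, 100), "AAA"),
            LandFeature(box(100, 0, 200, 100), "BBB"),
            LandFeature(box(200, 0, 300, 100), "AAA")]
    nodes = _labelled_nodes(land, [box(10, 10, 20, 20), box(210, 10, 220, 20)])
    assert len({n.portion_id for n in nodes}) == 2
    assert len({n.landmass_id for n in nodes}) == 1


def test_contiguous_country_single_portion():
    land = [LandFeature(box(0, 0, 100, 100), "AAA")]
    nodes = _labelled_nodes(land, [box(10, 10, 20, 20), box(50, 50, 60, 60)])
    assert len({n.portion_id for n in nodes}) == 1
    assert len({n.landmass_id for n in nodes}) == 1


# ---------------------------------------------------------------------------
# transboundary selection


def _tb_setup(gap_km):
    land = [LandFeature(box(0, 0, 100, 100), "AAA"),
            LandFeature(box(100, 0, 2000, 100), "BBB")]
    pa_boxes = [("AAA", box(80, 40, 90, 50)),
                ("BBB", box(90 + gap_km, 40, 100 + gap_km, 50))]
    nodes = clip_explode_filter(pa_boxes, land)
    return label_portions_landmasses(nodes, land)


@pytest.mark.parametrize("gap_km,included", [(499.0, True), (600.0, False)])
def test_transboundary_buffer_inclusion(gap_km, included):
    selected = select_transboundary(_tb_setup(gap_km), "AAA", buffer_km=500.0)
    foreign = [n for n in selected if n.iso3 == "BBB"]
    assert bool(foreign) is included
    assert all(n.is_transboundary for n in foreign)


def test_focal_nodes_never_flagged_transboundary():
    selected = select_transboundary(_tb_setup(100.0), "AAA")
    assert all(not n.is_transboundary for n in selected if n.iso3 == "AAA")


def test_country_with_zero_nodes_yields_empty_network():
    assert select_transboundary(_tb_setup(100.0), "CCC") == []


# ---------------------------------------------------------------------------
# distances


def brute_force_min_distance(poly_a, poly_b, n=2000):
    """Minimum distance over densified boundary point pairs."""
    def densify(poly):
        length = poly.exterior.length
        return np.array([
            poly.exterior.interpolate(t).coords[0]
            for t in np.linspace(0, length, n, endpoint=False)
        ])
    pa, pb = densify(poly_a), densify(poly_b)
    d2 = ((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2)
    return math.sqrt(d2.min())


def test_edge_distance_gap_and_contact():
    land = [LandFeature(box(0, 0, 100, 100), "AAA")]
    nodes = _labelled_nodes(
        land, [box(0, 0, 1, 1), box(6, 0, 7, 1)]  # 5 km gap
    )
    d = pairwise_edge_distances(nodes)
    assert list(d.values()) == pytest.approx([5.0])

    # corner-touching squares: contiguity, distance 0
    nodes = _labelled_nodes(land, [box(0, 0, 10, 10), box(10, 10, 20, 20)])
    if len(nodes) == 2:  # dissolve may merge edge-sharing, not corner-touching
        d = pairwise_edge_distances(nodes)
        assert list(d.values()) == pytest.approx([0.0])


def test_edge_distance_matches_densified_brute_force():
    rng = np.random.default_rng(3)
    land = [LandFeature(box(0, 0, 500, 500), "AAA")]
    rects = []
    for _ in range(3):
        x, y = rng.uniform(0, 400, 2)
        w, h = rng.uniform(10, 60, 2)
        rects.append(box(x, y, x + w, y + h))
    nodes = _labelled_nodes(land, rects)
    d = pairwise_edge_distances(nodes)
    geoms = {n.node_id: n.geometry for n in nodes}
    for (a, b), dist in d.items():
        if dist == 0.0:
            continue  # overlapping rectangles were dissolved/touching
        oracle = brute_force_min_distance(geoms[a], geoms[b])
        assert dist == pytest.approx(oracle, rel=0.01)


def test_triangle_inequality_spot_check():
    land = [LandFeature(box(0, 0, 500, 500), "AAA")]
    rects = [box(0, 0, 20, 20), box(100, 0, 130, 30), box(300, 0, 320, 20)]
    nodes = _labelled_nodes(land, rects)
    d = pairwise_edge_distances(nodes)
    ids = sorted(n.node_id for n in nodes)
    diam = {n.node_id: math.dist(n.geometry.bounds[:2], n.geometry.bounds[2:])
            for n in nodes}
    i, k, j = ids
    assert d[pair_key(i, j)] <= d[pair_key(i, k)] + d[pair_key(k, j)] + diam[k] + 1e-9


# ---------------------------------------------------------------------------
# country area and idempotence


def test_disputed_territory_excluded_from_country_area():
    land = [LandFeature(box(0, 0, 100, 100), "AAA"),
            LandFeature(box(100, 0, 150, 100), "AAA", disputed=True)]
    assert country_land_area(land, "AAA") == pytest.approx(10000.0)


def test_preprocess_idempotent_on_own_output():
    land = [LandFeature(box(0, 0, 200, 100), "AAA")]
    sites = [site("S1", box(10, 10, 40, 40)), site("S2", box(100, 10, 160, 60))]
    nodes1, d1 = preprocess_country(sites, land, "AAA")
    # feed the preprocessed polygons back in as sites
    sites2 = [RawPASite(n.node_id, n.geometry, n.iso3) for n in nodes1]
    nodes2, d2 = preprocess_country(sites2, land, "AAA")
    assert len(nodes1) == len(nodes2)
    assert sorted(n.area_km2 for n in nodes1) == pytest.approx(
        sorted(n.area_km2 for n in nodes2), abs=1e-6
    )
    assert sorted(d1.values()) == pytest.approx(sorted(d2.values()), abs=1e-6)
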