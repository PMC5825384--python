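"""File formats: GeoJSON layers, Conefor-style node/connection text files,
and CSV tables for indicators, classifications and groupings.

GeoJSON is the interchange vector format (coordinates are planar km in
synthetic worlds).  The abstract network is written as plain-text files in
the Conefor convention: a nodes file with ``node_id attribute`` per line
(attribute = area for focal-country nodes, 0 for transboundary ones) and a
connections file with ``id1 id2 distance_km`` per line, plus a CSV side
table carrying the iso3/portion/landmass labels.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from shapely.geometry import mapping, shape

from .classification import PriorityAssignment
from .geometry import LandFeature, PANodeGeom, RawPASite
from .indicators import IndicatorSet
from .network import PANode, pair_key

__all__ = [
    "write_pa_layer", "read_pa_layer",
    "write_land_layer", "read_land_layer",
    "write_conefor", "read_conefor",
    "indicators_to_frame", "write_indicators", "read_indicators",
    "write_classification",
]


# ---------------------------------------------------------------------------
# GeoJSON layers


def _feature(geom, properties: dict) -> dict:
    return {"type": "Feature", "geometry": mapping(geom), "properties": properties}


def _dump(features: list[dict], path: str | Path) -> None:
    fc = {"type": "FeatureCollection", "features": features}
    Path(path).write_text(json.dumps(fc, sort_keys=True) + "\n")


def _load(path: str | Path) -> list[dict]:
    fc = json.loads(Path(path).read_text())
    if fc.get("type") != "FeatureCollection":
        raise ValueError(f"{path} is not a GeoJSON FeatureCollection")
    return fc["features"]


def write_pa_layer(sites: list[RawPASite], path: str | Path) -> None:
    _dump(
        [
            _feature(
                s.geometry,
                {
                    "site_id": s.site_id,
                    "iso3": s.iso3,
                    "status": s.status,
                    "designation_type": s.designation_type,
                    "reported_area_km2": s.reported_area_km2,
                    "iucn_category": s.iucn_category,
                },
            )
            for s in sites
        ],
        path,
    )


def read_pa_layer(path: str | Path) -> list[RawPASite]:
    sites = []
    for f in _load(path):
        p = f["properties"]
        sites.append(
            RawPASite(
                site_id=p["site_id"],
                geometry=shape(f["geometry"]),
                iso3=p["iso3"],
                status=p.get("status", "Designated"),
                designation_type=p.get("designation_type", ""),
                reported_area_km2=p.get("reported_area_km2"),
                iucn_category=p.get("iucn_category"),
            )
        )
    return sites


def write_land_layer(land: list[LandFeature], path: str | Path) -> None:
    _dump(
        [
            _feature(f.geometry, {"iso3": f.iso3, "disputed": f.disputed})
            for f in land
        ],
        path,
    )


def read_land_layer(path: str | Path) -> list[LandFeature]:
    return [
        LandFeature(
            geometry=shape(f["geometry"]),
            iso3=f["properties"]["iso3"],
            disputed=bool(f["properties"].get("disputed", False)),
        )
        for f in _load(path)
    ]


# ---------------------------------------------------------------------------
# Conefor-style network files


def write_conefor(
    nodes: list[PANodeGeom | PANode],
    distances: dict[tuple[str, str], float],
    nodes_path: str | Path,
    connections_path: str | Path,
    labels_path: str | Path | None = None,
) -> None:
    """Write node-attribute and pairwise-distance text files.

    The node attribute is the PA area for focal nodes and 0 for
    transboundary nodes; distances are km.  ``labels_path`` receives the
    iso3 / portion / landmass side table as CSV.
    """
    lines = []
    for n in sorted(nodes, key=lambda n: n.node_id):
        area = n.area_km2 if isinstance(n, PANodeGeom) else n.area
        attr = 0.0 if n.is_transboundary else area
        lines.append(f"{n.node_id} {attr:.9g}")
    Path(nodes_path).write_text("\n".join(lines) + "\n")

    lines = [
        f"{a} {b} {d:.9g}"
        for (a, b), d in sorted(distances.items())
    ]
    Path(connections_path).write_text("\n".join(lines) + "\n")

    if labels_path is not None:
        rows = []
        for n in sorted(nodes, key=lambda n: n.node_id):
            area = n.area_km2 if isinstance(n, PANodeGeom) else n.area
            rows.append(
                {
                    "node_id": n.node_id,
                    "iso3": n.iso3,
                    "area_km2": area,
                    "portion_id": n.portion_id,
                    "landmass_id": n.landmass_id,
                    "is_transboundary": n.is_transboundary,
                }
            )
        pd.DataFrame(rows).to_csv(labels_path, index=False)


def read_conefor(
    nodes_path: str | Path,
    connections_path: str | Path,
    labels_path: str | Path | None = None,
) -> tuple[list[PANode], dict[tuple[str, str], float]]:
    """Read a Conefor-style network back into abstract nodes + distances.

    Without a labels table, every node is treated as focal (attribute > 0)
    or transboundary (attribute 0) in a single portion of one landmass, the
    plain single-country setting of a Conefor run.
    """
    labels = None
    if labels_path is not None:
        labels = pd.read_csv(labels_path, dtype={"node_id": str}).set_index("node_id")

    nodes: list[PANode] = []
    for line in Path(nodes_path).read_text().splitlines():
        if not line.strip():
            continue
        node_id, attr = line.split()
        attr = float(attr)
        if labels is not None:
            row = labels.loc[node_id]
            nodes.append(
                PANode(
                    node_id=node_id,
                    area=float(row["area_km2"]),
                    iso3=str(row["iso3"]),
                    portion_id=str(row["portion_id"]),
                    landmass_id=str(row["landmass_id"]),
                    is_transboundary=bool(row["is_transboundary"]),
                )
            )
        else:
            nodes.append(
                PANode(
                    node_id=node_id,
                    area=attr,
                    iso3="",
                    portion_id="P0",
                    landmass_id="L0",
                    is_transboundary=attr == 0.0,
                )
            )

    distances: dict[tuple[str, str], float] = {}
    for line in Path(connections_path).read_text().splitlines():
        if not line.strip():
            continue
        a, b, d = line.split()
        distances[pair_key(a, b)] = float(d)
    return nodes, distances


# ---------------------------------------------------------------------------
# CSV tables


def indicators_to_frame(indicator_sets: list[IndicatorSet]) -> pd.DataFrame:
    return pd.DataFrame([s.as_dict() for s in indicator_sets],
                        columns=list(IndicatorSet.COLUMNS))


def write_indicators(indicator_sets: list[IndicatorSet], path: str | Path) -> None:
    indicators_to_frame(indicator_sets).to_csv(path, index=False)


def read_indicators(path: str | Path) -> list[IndicatorSet]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        kwargs = {c: row[c] for c in IndicatorSet.COLUMNS}
        kwargs["iso3"] = str(kwargs["iso3"])
        kwargs["no_connected_land"] = bool(kwargs["no_connected_land"])
        out.append(IndicatorSet(**kwargs))
    return out


def write_classification(
    assignments: list[PriorityAssignment], path: str | Path
) -> None:
    rows = []
    for a in assignments:
        rows.append(
            {
                "iso3": a.iso3,
                "a1": a.a1, "a2": a.a2, "b1": a.b1, "b2": a.b2, "b3": a.b3,
                "c": a.c,
                "labels": "+".join(a.labels),
                **{f"threshold_{k}": v for k, v in a.diagnostics.items()},
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
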