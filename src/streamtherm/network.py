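"""River network and catchment vector data.

A :class:`RiverNetwork` is a set of reaches (polylines ordered upstream to
downstream) with per-reach drainage areas and downstream connectivity, plus
the measurement-site outlets.  Vectors are read and written as GeoJSON
FeatureCollections in planar metric coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from shapely.geometry import LineString, Point, Polygon, mapping, shape

__all__ = [
    "Reach",
    "RiverNetwork",
    "read_network_geojson",
    "write_network_geojson",
    "read_catchments_geojson",
    "write_catchments_geojson",
]


@dataclass
class Reach:
    """One channel reach, vertices ordered upstream -> downstream.

    ``drainage_km2`` is the drainage area at the reach's downstream end.
    ``downstream`` is the id of the receiving reach (None at an outlet).
    """

    reach_id: str
    vertices: np.ndarray  # (n, 2) planar coordinates, meters
    drainage_km2: float
    downstream: str | None = None

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 2:
            raise ValueError(f"reach {self.reach_id}: vertices must be an (n>=2, 2) array")
        if self.drainage_km2 < 0:
            raise ValueError(f"reach {self.reach_id}: negative drainage area")

    @property
    def line(self) -> LineString:
        return LineString(self.vertices)

    @property
    def length(self) -> float:
        return float(self.line.length)

    @property
    def chord(self) -> float:
        """Straight distance between the reach endpoints ("mean axis" length)."""
        return float(np.hypot(*(self.vertices[-1] - self.vertices[0])))

    def sinuosity(self) -> float:
        if self.chord <= 1e-9 * max(1.0, self.length):
            raise ValueError(f"reach {self.reach_id}: closed loop (zero chord)")
        return self.length / self.chord


@dataclass
class RiverNetwork:
    """Reaches keyed by id, with site outlets.

    ``sites`` maps site_id -> (x, y) outlet coordinates on the network.
    The reach graph must be acyclic with drainage area non-decreasing
    downstream; :meth:`validate` enforces both.
    """

    reaches: dict[str, Reach]
    sites: dict[str, tuple[float, float]] = field(default_factory=dict)

    def validate(self) -> None:
        for r in self.reaches.values():
            if r.downstream is not None:
                if r.downstream not in self.reaches:
                    raise ValueError(f"reach {r.reach_id}: unknown downstream reach {r.downstream}")
                down = self.reaches[r.downstream]
                if down.drainage_km2 < r.drainage_km2 - 1e-9:
                    raise ValueError(
                        f"drainage area decreases downstream: {r.reach_id} -> {r.downstream}"
                    )
        # acyclicity by walking every chain
        for rid in self.reaches:
            seen = set()
            cur: str | None = rid
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"cycle in reach connectivity at {cur}")
                seen.add(cur)
                cur = self.reaches[cur].downstream

    def upstream_reaches(self, reach_id: str) -> list[str]:
        """Ids of reaches draining (directly or indirectly) into ``reach_id``, inclusive."""
        incoming: dict[str, list[str]] = {rid: [] for rid in self.reaches}
        for r in self.reaches.values():
            if r.downstream is not None:
                incoming[r.downstream].append(r.reach_id)
        out: list[str] = []
        stack = [reach_id]
        while stack:
            cur = stack.pop()
            out.append(cur)
            stack.extend(incoming[cur])
        return out

    def nearest_reach(self, x: float, y: float) -> str:
        p = Point(x, y)
        return min(self.reaches.values(), key=lambda r: r.line.distance(p)).reach_id


# ---------------------------------------------------------------------------
# GeoJSON I/O


def write_network_geojson(net: RiverNetwork, path: str | Path) -> None:
    feats = []
    for r in net.reaches.values():
        feats.append(
            {
                "type": "Feature",
                "geometry": mapping(r.line),
                "properties": {
                    "reach_id": r.reach_id,
                    "drainage_km2": r.drainage_km2,
                    "downstream": r.downstream,
                },
            }
        )
    for sid, (x, y) in net.sites.items():
        feats.append(
            {
                "type": "Feature",
                "geometry": mapping(Point(x, y)),
                "properties": {"site_id": sid},
            }
        )
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


def read_network_geojson(path: str | Path) -> RiverNetwork:
    obj = json.loads(Path(path).read_text())
    reaches: dict[str, Reach] = {}
    sites: dict[str, tuple[float, float]] = {}
    for feat in obj["features"]:
        geom = shape(feat["geometry"])
        props = feat.get("properties") or {}
        if geom.geom_type == "LineString":
            if "drainage_km2" not in props:
                raise ValueError(
                    f"reach feature {props.get('reach_id', '?')} missing 'drainage_km2' property"
                )
            r = Reach(
                reach_id=str(props.get("reach_id", len(reaches))),
                vertices=np.asarray(geom.coords, dtype=float),
                drainage_km2=float(props["drainage_km2"]),
                downstream=props.get("downstream"),
            )
            reaches[r.reach_id] = r
        elif geom.geom_type == "Point":
            sites[str(props["site_id"])] = (geom.x, geom.y)
    net = RiverNetwork(reaches=reaches, sites=sites)
    net.validate()
    return net


def write_catchments_geojson(catchments: dict[str, Polygon], path: str | Path) -> None:
    feats = [
        {
            "type": "Feature",
            "geometry": mapping(poly),
            "properties": {"site_id": sid},
        }
        for sid, poly in catchments.items()
    ]
    Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


def read_catchments_geojson(path: str | Path) -> dict[str, Polygon]:
    obj = json.loads(Path(path).read_text())
    out: dict[str, Polygon] = {}
    for feat in obj["features"]:
        props = feat.get("properties") or {}
        if "site_id" not in props:
            raise ValueError("catchment feature missing 'site_id' property")
        out[str(props["site_id"])] = shape(feat["geometry"])
    return out
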