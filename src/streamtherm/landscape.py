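"""The 15 environmental variables per site and spatial scale.

Station-scale variables: baseflow index (BFI), channel slope (SLOP),
elevation (ELEV), watershed area (AREA), water level (LEVEL).  Stream
network-dependent: shade on the water surface (SHADE) and channel
sinuosity (SINUO).  Area-dependent: the eight aggregated land-cover
proportions (AGRI, ARTI, BROAD, HERBA, FORESTS, NEEDLE, OTHER, WATER).

Six nested spatial footprints are evaluated per site: the full upstream
catchment (``CA``), its intersection with 1 km and 2 km discs around the
site (``buff_1``, ``buff_2``), a 50 m riparian corridor along the upstream
network (``ripa``) and the corridor clipped to the discs (``buff_1_ripa``,
``buff_2_ripa``).

All zonal statistics are raster-based: footprints are rasterized on the
site's DEM window by cell-center containment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon
from shapely.ops import unary_union

from .grids import RasterGrid
from .network import RiverNetwork

__all__ = [
    "SCALES",
    "LANDCOVER_CLASSES",
    "SolarPosition",
    "ScaleMaskSet",
    "compute_bfi",
    "solar_position",
    "hillshade_angle",
    "water_surface_mask",
    "shade_metric",
    "landcover_proportions",
    "network_sinuosity",
    "channel_slope",
    "build_scale_masks",
    "assemble_landscape_table",
]

log = logging.getLogger(__name__)

SCALES = ["CA", "buff_1", "buff_2", "ripa", "buff_1_ripa", "buff_2_ripa"]

#: Raster code -> aggregated land-cover category.
LANDCOVER_CLASSES = {
    1: "AGRI", 2: "ARTI", 3: "BROAD", 4: "HERBA",
    5: "FORESTS", 6: "NEEDLE", 7: "OTHER", 8: "WATER",
}
CATEGORY_NAMES = list(LANDCOVER_CLASSES.values())

#: Shade/sinuosity are computed on the watercourse, which is identical
#: within each of these footprint pairs.
_PAIRED_SCALES = {"ripa": "CA", "buff_1_ripa": "buff_1", "buff_2_ripa": "buff_2"}


# ---------------------------------------------------------------------------
# Baseflow index (smoothed-minima separation)


def compute_bfi(
    discharge,
    block_days: int = 5,
    turning_factor: float = 0.9,
) -> float:
    """Baseflow index by the smoothed-minima separation.

    The daily flow record is cut into non-overlapping ``block_days``-day
    blocks; the minimum of each block is a candidate point, and a block
    minimum m_i is a turning point when ``turning_factor * m_i`` does not
    exceed either neighbouring minimum.  The first and last block minima
    anchor the baseline.  The baseflow line interpolates linearly between
    turning points (in time, at the day each minimum occurred), is capped
    at the observed flow, and BFI is the ratio of baseflow volume to total
    flow volume over the anchored span.  Always in [0, 1].
    """
    q = np.asarray(pd.Series(discharge).to_numpy(), dtype=float)
    if np.isnan(q).any():
        raise ValueError("discharge contains missing values")
    if (q <= 0).any():
        raise ValueError("discharge must be strictly positive")
    n_blocks = len(q) // block_days
    if n_blocks < 3:
        raise ValueError(
            f"series too short: {len(q)} days gives {n_blocks} blocks of {block_days}, need >= 3"
        )
    mins = np.empty(n_blocks)
    min_days = np.empty(n_blocks, dtype=int)
    for i in range(n_blocks):
        blk = q[i * block_days : (i + 1) * block_days]
        j = int(np.argmin(blk))
        mins[i] = blk[j]
        min_days[i] = i * block_days + j
    turning = np.zeros(n_blocks, dtype=bool)
    turning[0] = turning[-1] = True  # anchors
    for i in range(1, n_blocks - 1):
        if turning_factor * mins[i] <= mins[i - 1] and turning_factor * mins[i] <= mins[i + 1]:
            turning[i] = True
    tp_days = min_days[turning]
    tp_vals = mins[turning]
    days = np.arange(tp_days[0], tp_days[-1] + 1)
    base = np.interp(days, tp_days, tp_vals)
    base = np.minimum(base, q[days])
    total = float(q[days].sum())
    return float(base.sum() / total)


# ---------------------------------------------------------------------------
# Solar geometry and hillshading


@dataclass
class SolarPosition:
    """Sun position at solar noon for one date and latitude."""

    date: pd.Timestamp
    latitude_deg: float
    declination_deg: float
    elevation_deg: float
    azimuth_deg: float = 180.0


def solar_position(date, latitude_deg: float) -> SolarPosition:
    """Solar-noon sun position from the standard day-of-year declination.

    declination = 23.44 sin(2 pi (284 + n) / 365); noon elevation =
    90 - latitude + declination; azimuth due south (180 deg) in the
    northern hemisphere.  Polar latitudes (|lat| >= 66.5) are rejected.
    """
    if abs(latitude_deg) >= 66.5:
        raise ValueError("polar latitudes not supported (|latitude| must be < 66.5 deg)")
    d = pd.Timestamp(date)
    n = d.dayofyear
    decl = 23.44 * math.sin(math.radians(360.0 * (284 + n) / 365.0))
    elev = 90.0 - latitude_deg + decl
    return SolarPosition(d, latitude_deg, decl, elev, 180.0)


def _horn_gradients(z: np.ndarray, cellsize: float) -> tuple[np.ndarray, np.ndarray]:
    """8-neighbour (Horn) finite-difference gradients; borders replicate."""
    zp = np.pad(z, 1, mode="edge")
    nw, n_, ne = zp[:-2, :-2], zp[:-2, 1:-1], zp[:-2, 2:]
    w_, e_ = zp[1:-1, :-2], zp[1:-1, 2:]
    sw, s_, se = zp[2:, :-2], zp[2:, 1:-1], zp[2:, 2:]
    dzdx = ((ne + 2 * e_ + se) - (nw + 2 * w_ + sw)) / (8 * cellsize)
    # row index increases southward; northward gradient flips the sign
    dzdy = ((nw + 2 * n_ + ne) - (sw + 2 * s_ + se)) / (8 * cellsize)
    return dzdx, dzdy


def hillshade_angle(
    dem: RasterGrid,
    sun: SolarPosition,
    cast_shadows: bool = True,
    max_shadow_distance: float = 200.0,
) -> RasterGrid:
    """Solar-incidence shade angle per cell, in degrees within [0, 90].

    The shade angle is the angle between the surface normal and the sun
    direction (0 = sun perpendicular to the surface, 90 = grazing or in
    shadow).  With ``cast_shadows`` a ray-march along the sun azimuth sets
    the angle to 90 wherever the local horizon exceeds the sun elevation,
    scanning out to ``max_shadow_distance`` meters.
    """
    if dem.nrows < 3 or dem.ncols < 3:
        raise ValueError("DEM must be at least 3x3 cells")
    z = dem.values
    dzdx, dzdy = _horn_gradients(z, dem.cellsize)
    norm = np.sqrt(dzdx**2 + dzdy**2 + 1.0)
    az = math.radians(sun.azimuth_deg)
    el = math.radians(sun.elevation_deg)
    sx, sy, sz = math.sin(az) * math.cos(el), math.cos(az) * math.cos(el), math.sin(el)
    cos_inc = (-dzdx * sx - dzdy * sy + sz) / norm
    shade = np.degrees(np.arccos(np.clip(cos_inc, -1.0, 1.0)))
    shade = np.clip(shade, 0.0, 90.0)

    if cast_shadows and sun.elevation_deg > 0:
        ux, uy = math.sin(az), math.cos(az)  # horizontal unit vector toward the sun
        tan_el = math.tan(el)
        n_steps = max(1, int(math.ceil(max_shadow_distance / dem.cellsize)))
        nrows, ncols = z.shape
        shadowed = np.zeros_like(z, dtype=bool)
        for k in range(1, n_steps + 1):
            dc = int(round(k * ux))
            dr = int(round(-k * uy))  # northward = decreasing row
            if (dc == 0 and dr == 0) or abs(dr) >= nrows or abs(dc) >= ncols:
                continue
            dist = math.hypot(dc, dr) * dem.cellsize
            zs = np.full_like(z, -np.inf)
            r0, r1 = max(0, -dr), min(nrows, nrows - dr)
            c0, c1 = max(0, -dc), min(ncols, ncols - dc)
            if r0 >= r1 or c0 >= c1:
                continue
            zs[r0:r1, c0:c1] = z[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
            shadowed |= (zs - z) / dist > tan_el
        shade = np.where(shadowed, 90.0, shade)
    return dem.like(shade)


# ---------------------------------------------------------------------------
# Water surface and footprints


def water_surface_mask(
    net: RiverNetwork,
    template: RasterGrid,
    reach_ids: list[str] | None = None,
    min_drainage_km2: float = 1.0,
    mapped_drainage_km2: float = 50.0,
    small_halfwidth_m: float = 2.0,
) -> np.ndarray:
    """Boolean raster of water-surface cells on the template grid.

    Reaches below ``min_drainage_km2`` are excluded.  Reaches between the
    thresholds get a fixed ``small_halfwidth_m`` corridor around the channel
    line; larger reaches use a drainage-scaled width (0.5 sqrt(A_km2) m,
    never narrower than the fixed corridor) standing in for a mapped water
    polygon.  Cells are selected by center containment.
    """
    reaches = [net.reaches[r] for r in (reach_ids or list(net.reaches))]
    geoms = []
    for r in reaches:
        if r.drainage_km2 < min_drainage_km2:
            continue
        if r.drainage_km2 < mapped_drainage_km2:
            hw = small_halfwidth_m
        else:
            hw = max(small_halfwidth_m, 0.5 * math.sqrt(r.drainage_km2))
        geoms.append(r.line.buffer(hw, cap_style="flat"))
    if not geoms:
        return np.zeros(template.values.shape, dtype=bool)
    return _rasterize(unary_union(geoms), template)


def _rasterize(geom, template: RasterGrid) -> np.ndarray:
    """Cell-center containment mask of a shapely geometry."""
    X, Y = template.cell_centers()
    return shapely.contains_xy(geom, X.ravel(), Y.ravel()).reshape(template.values.shape)


@dataclass
class ScaleMaskSet:
    """The six per-site footprints, as polygons and boolean rasters."""

    site_id: str
    template: RasterGrid
    polygons: dict[str, Polygon]
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def validate(self) -> None:
        m = self.masks
        for k in SCALES:
            if k not in m:
                raise ValueError(f"missing scale mask {k}")
        if (m["ripa"] & ~m["CA"]).any():
            raise ValueError("ripa must be contained in CA")
        for k in ("buff_1", "buff_2"):
            if (m[k] & ~m["CA"]).any():
                raise ValueError(f"{k} must be contained in CA")
        if (m["buff_1"] & ~m["buff_2"]).any():
            raise ValueError("buff_1 must be contained in buff_2")
        for rk, bk in (("buff_1_ripa", "buff_1"), ("buff_2_ripa", "buff_2")):
            if (m[rk] != (m["ripa"] & m[bk])).any():
                raise ValueError(f"{rk} must equal ripa & {bk} cell-for-cell")


def build_scale_masks(
    catchment: Polygon,
    site_xy: tuple[float, float],
    net: RiverNetwork,
    template: RasterGrid,
    upstream_reach_ids: list[str],
    radii_m: tuple[float, float] = (1000.0, 2000.0),
    corridor_halfwidth_m: float = 50.0,
) -> ScaleMaskSet:
    """Assemble the six spatial-scale footprints for one site.

    Discs are centered on the measurement site and clipped to the upstream
    catchment; the riparian corridor buffers the upstream network by
    ``corridor_halfwidth_m`` on each side and is clipped the same way.
    """
    site = Point(*site_xy)
    lines = [net.reaches[r].line for r in upstream_reach_ids]
    corridor = unary_union([ln.buffer(corridor_halfwidth_m, cap_style="flat") for ln in lines])
    polys = {
        "CA": catchment,
        "buff_1": catchment.intersection(site.buffer(radii_m[0], quad_segs=64)),
        "buff_2": catchment.intersection(site.buffer(radii_m[1], quad_segs=64)),
        "ripa": catchment.intersection(corridor),
    }
    polys["buff_1_ripa"] = polys["ripa"].intersection(polys["buff_1"])
    polys["buff_2_ripa"] = polys["ripa"].intersection(polys["buff_2"])
    masks = {k: _rasterize(p, template) for k, p in polys.items()}
    # enforce the set identities exactly on the rasterized masks
    masks["ripa"] &= masks["CA"]
    masks["buff_1"] &= masks["buff_2"]
    masks["buff_1"] &= masks["CA"]
    masks["buff_2"] &= masks["CA"]
    masks["buff_1_ripa"] = masks["ripa"] & masks["buff_1"]
    masks["buff_2_ripa"] = masks["ripa"] & masks["buff_2"]
    ms = ScaleMaskSet(site_id="", template=template, polygons=polys, masks=masks)
    ms.validate()
    return ms


# ---------------------------------------------------------------------------
# Zonal metrics


def shade_metric(shade: RasterGrid, water_mask: np.ndarray, scale_mask: np.ndarray) -> float:
    """Median shade angle over water-surface cells inside the footprint.

    Returns NaN (with a warning) when the intersection is empty.
    """
    sel = water_mask & scale_mask & shade.mask_valid()
    if not sel.any():
        log.warning("shade_metric: empty water x footprint intersection")
        return float("nan")
    return float(np.median(shade.values[sel]))


def landcover_proportions(
    landcover: RasterGrid,
    scale_mask: np.ndarray,
    class_mapping: dict[int, int] | None = None,
) -> dict[str, float]:
    """Percentage of each of the eight categories over the footprint.

    ``class_mapping`` optionally remaps raw raster codes (e.g. an 18-class
    product) onto the eight category codes first; any code present but not
    mapped raises an error naming it.  Percentages sum to 100.
    """
    sel = scale_mask & landcover.mask_valid()
    if not sel.any():
        raise ValueError("empty footprint for land-cover proportions")
    codes = landcover.values[sel].astype(int)
    if class_mapping is not None:
        mapped = np.full_like(codes, -1)
        for src, dst in class_mapping.items():
            mapped[codes == src] = dst
        if (mapped == -1).any():
            bad = sorted(set(codes[mapped == -1].tolist()))
            raise ValueError(f"unmapped land-cover code(s): {bad}")
        codes = mapped
    unknown = sorted(set(codes.tolist()) - set(LANDCOVER_CLASSES))
    if unknown:
        raise ValueError(f"unmapped land-cover code(s): {unknown}")
    n = len(codes)
    return {
        name: 100.0 * float(np.count_nonzero(codes == code)) / n
        for code, name in LANDCOVER_CLASSES.items()
    }


def network_sinuosity(net: RiverNetwork, upstream_reach_ids: list[str], footprint: Polygon) -> float:
    """Length-weighted mean reach sinuosity over the footprint.

    Each upstream reach intersecting the footprint contributes its own
    sinuosity (polyline length over straight endpoint distance), weighted
    by the length of channel it contributes inside the footprint.
    """
    weights, sinus = [], []
    for rid in upstream_reach_ids:
        r = net.reaches[rid]
        inter = r.line.intersection(footprint)
        if inter.is_empty or inter.length == 0:
            continue
        weights.append(inter.length)
        sinus.append(r.sinuosity())
    if not weights:
        raise ValueError("no upstream reach intersects the footprint")
    w = np.asarray(weights)
    return float(np.average(sinus, weights=w))


def _walk(net: RiverNetwork, reach_id: str, pos: float, distance: float, direction: str):
    """Walk ``distance`` meters along the network from (reach, position).

    direction 'down' follows downstream links; 'up' follows the largest-
    drainage upstream reach at junctions.  Returns (endpoint Point,
    distance actually walked).
    """
    walked = 0.0
    cur = net.reaches[reach_id]
    cur_pos = pos
    while True:
        if direction == "down":
            avail = cur.line.length - cur_pos
        else:
            avail = cur_pos
        if walked + avail >= distance:
            step = distance - walked
            new_pos = cur_pos + step if direction == "down" else cur_pos - step
            return cur.line.interpolate(new_pos), distance
        walked += avail
        if direction == "down":
            if cur.downstream is None:
                return cur.line.interpolate(cur.line.length), walked
            cur = net.reaches[cur.downstream]
            cur_pos = 0.0
        else:
            ups = [r for r in net.reaches.values() if r.downstream == cur.reach_id]
            if not ups:
                return cur.line.interpolate(0.0), walked
            cur = max(ups, key=lambda r: r.drainage_km2)
            cur_pos = cur.line.length


def channel_slope(
    dem: RasterGrid,
    net: RiverNetwork,
    site_xy: tuple[float, float],
    distance_m: float = 4000.0,
) -> float:
    """Channel slope (%) over ~``distance_m`` of channel centered on the site.

    Walks half the distance upstream (main stem at junctions) and half
    downstream along the network, samples the DEM at both endpoints and
    divides the drop by the channel length actually walked (truncated with
    a warning where the network ends sooner).
    """
    p = Point(*site_xy)
    rid = net.nearest_reach(*site_xy)
    reach = net.reaches[rid]
    pos = reach.line.project(p)
    if reach.line.distance(p) > 10 * max(1.0, dem.cellsize):
        raise ValueError("site does not lie on the river network")
    up_pt, up_d = _walk(net, rid, pos, distance_m / 2, "up")
    down_pt, down_d = _walk(net, rid, pos, distance_m / 2, "down")
    total = up_d + down_d
    if total < distance_m - 1e-6:
        log.warning("channel_slope: only %.0f m of channel available (wanted %.0f)", total, distance_m)
    if total == 0:
        raise ValueError("no channel length available at the site")
    z_up = dem.value_at(up_pt.x, up_pt.y)
    z_down = dem.value_at(down_pt.x, down_pt.y)
    return 100.0 * (z_up - z_down) / total


# ---------------------------------------------------------------------------
# Table assembly


def assemble_landscape_table(
    dem: RasterGrid,
    landcover: RasterGrid,
    net: RiverNetwork,
    catchments: dict[str, Polygon],
    series_map,
    event_dates,
    latitude_deg: float = 50.0,
    radii_m: tuple[float, float] = (1000.0, 2000.0),
    corridor_halfwidth_m: float = 50.0,
    cast_shadows: bool = True,
    bfi_block_days: int = 5,
    bfi_turning_factor: float = 0.9,
    slope_distance_m: float = 4000.0,
    cell_margin_m: float = 100.0,
    class_mapping: dict[int, int] | None = None,
) -> pd.DataFrame:
    """Compute the full 15-variable record per site and spatial scale.

    Station-scale variables (AREA, SLOP, ELEV, LEVEL, BFI) are replicated
    across scales; SHADE and SINUO are computed on the watercourse and are
    identical within the CA/ripa, buff_1/buff_1_ripa and buff_2/buff_2_ripa
    pairs; SHADE is the per-event median shade averaged over the event
    dates.  Missing metrics become NaN; the row is retained and logged.
    """
    dates = [pd.Timestamp(d) for d in event_dates]
    suns = [solar_position(d, latitude_deg) for d in dates]
    rows = []
    for site_id, xy in net.sites.items():
        if site_id not in catchments:
            log.warning("site %s has no catchment polygon; skipped", site_id)
            continue
        catch = catchments[site_id]
        xmin, ymin, xmax, ymax = catch.bounds
        m = cell_margin_m
        win_dem = dem.window(xmin - m, ymin - m, xmax + m, ymax + m)
        win_lc = landcover.window(xmin - m, ymin - m, xmax + m, ymax + m)
        outlet_reach = net.nearest_reach(*xy)
        upstream = net.upstream_reaches(outlet_reach)
        ms = build_scale_masks(
            catch, xy, net, win_dem, upstream, radii_m, corridor_halfwidth_m
        )
        wmask = water_surface_mask(net, win_dem, reach_ids=upstream)

        # station-scale variables (identical across footprints)
        series = series_map[site_id]
        station = {
            "AREA": catch.area / 1e6,
            "SLOP": channel_slope(dem, net, xy, slope_distance_m),
            "ELEV": dem.value_at(*xy),
            "BFI": compute_bfi(
                series.data["q"].dropna(), bfi_block_days, bfi_turning_factor
            ),
        }
        in_range = [d for d in dates if d in series.data.index]
        station["LEVEL"] = (
            float(series.data.loc[in_range, "level"].mean()) if in_range else float("nan")
        )

        # watercourse variables per footprint group (CA, buff_1, buff_2)
        shade_grids = [
            hillshade_angle(win_dem, sun, cast_shadows=cast_shadows) for sun in suns
        ]
        group_vals: dict[str, dict[str, float]] = {}
        for scale in ("CA", "buff_1", "buff_2"):
            per_event = [shade_metric(g, wmask, ms.masks[scale]) for g in shade_grids]
            shade_mean = float(np.nanmean(per_event)) if per_event else float("nan")
            try:
                sinu = network_sinuosity(net, upstream, ms.polygons[scale])
            except ValueError as exc:
                log.warning("site %s %s: %s", site_id, scale, exc)
                sinu = float("nan")
            group_vals[scale] = {"SHADE": shade_mean, "SINUO": sinu}

        for scale in SCALES:
            grp = group_vals[_PAIRED_SCALES.get(scale, scale)]
            try:
                props = landcover_proportions(win_lc, ms.masks[scale], class_mapping)
            except ValueError as exc:
                log.warning("site %s %s: %s", site_id, scale, exc)
                props = {name: float("nan") for name in CATEGORY_NAMES}
            rows.append({"site": site_id, "scale": scale, **grp, **props, **station})
    cols = ["site", "scale", "SHADE", "SINUO", *CATEGORY_NAMES, "AREA", "SLOP", "LEVEL", "ELEV", "BFI"]
    df = pd.DataFrame(rows)
    return df[cols] if not df.empty else pd.DataFrame(columns=cols)
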