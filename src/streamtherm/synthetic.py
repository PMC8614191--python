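"""Synthetic study generator with known ground truth.

Builds a complete stand-in for the monitoring study: a dendritic river
network with nested catchments laid out on a tiled planar domain, a
surface model carrying riparian canopy, an eight-category land-cover
raster, daily air temperature with scheduled heat waves, daily discharge
with a dialable baseflow share, and daily maximum water temperature
generated by forward-Euler stepping of the thermal-dynamics model with
per-site true parameters.

The true parameters are a linear function of the *measured* standardized
landscape covariates (the same quantities the analysis later computes), so
the full pipeline can recover the generating relationships exactly in the
noise-free limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Polygon, box

from .config import PREDICTOR_ORDER, SimConfig
from .grids import RasterGrid
from .landscape import assemble_landscape_table
from .network import Reach, RiverNetwork
from .series import DailySiteSeries
from .thermal import WINDOW_HALF, ThermalDynamicsModel

__all__ = [
    "SyntheticTruth",
    "SyntheticStudy",
    "generate_network",
    "generate_terrain_and_landcover",
    "generate_climate",
    "generate_discharge",
    "simulate_water_temperature",
    "make_dataset",
    "make_regression_table",
]

_TRIB_FRACS = (0.25, 0.5, 0.75)
_MARGIN = 100.0  # tile margin around each basin (m)


@dataclass
class BasinGeometry:
    """Internal per-basin layout (one basin may carry several sites)."""

    basin_id: int
    x0: float          # upstream end of the channel box
    y0: float          # southern edge
    length: float      # along-stem extent (m)
    width: float       # across-valley extent (m)
    amplitude: float   # meander amplitude (m)
    wavelength: float
    tree_density: float
    base_elev: float
    quickflow_share: float
    gradient: float = 0.004  # along-channel elevation gradient (m/m)

    def stem_y(self, x) -> np.ndarray:
        xx = np.clip(np.asarray(x, float), self.x0, self.x0 + self.length)
        if self.amplitude == 0:
            return np.full_like(xx, self.y0 + self.width / 2.0)
        return self.y0 + self.width / 2.0 + self.amplitude * np.sin(
            2.0 * math.pi * (xx - self.x0) / self.wavelength
        )


@dataclass
class SyntheticTruth:
    """Ground truth written alongside every synthetic dataset."""

    covariates: pd.DataFrame          # site x 15 measured covariates (raw units)
    covariates_z: pd.DataFrame        # standardized covariates used in the link
    params: pd.DataFrame              # site-level true (a, b, c)
    event_params: pd.DataFrame        # (site, date) true triples actually used
    extreme_dates: list[str]
    bfi_target: pd.Series             # per-site baseflow share 1 - quickflow share
    n_floored: int = 0                # sites whose a or b hit the positivity floor
    n_stability_redraws: int = 0      # site draws redrawn for Euler stability

    def validate(self) -> None:
        if (self.params[["a", "b"]] < 0).any().any():
            raise ValueError("true day/night sensitivities must be non-negative")


@dataclass
class SyntheticStudy:
    config: SimConfig
    network: RiverNetwork
    sites: pd.DataFrame               # site, x, y, basin
    catchments: dict[str, Polygon]
    basins: list[BasinGeometry]
    dem: RasterGrid
    landcover: RasterGrid
    series: dict[str, DailySiteSeries] = field(default_factory=dict)
    truth: SyntheticTruth | None = None

    @property
    def extreme_dates(self) -> list[str]:
        return [w.date for w in self.config.heat_waves]


# ---------------------------------------------------------------------------
# Network and catchments


def _snap(value: float, cell: float) -> float:
    return max(cell, round(value / cell) * cell)


def generate_network(
    config: SimConfig, rng: np.random.Generator
) -> tuple[RiverNetwork, pd.DataFrame, dict[str, Polygon], list[BasinGeometry]]:
    """Dendritic network of tiled basins with nested site catchments.

    Each basin is a rectangular valley with a meandering main stem flowing
    west to east and straight tributaries; drainage area grows strictly
    downstream.  Basin rectangles snap to the raster cell size so catchment
    polygon areas equal their rasterized cell counts exactly.
    """
    config.validate()
    cell = config.cell_size
    spb = config.sites_per_basin
    n_basins = math.ceil(config.n_sites / spb)
    lo, hi = config.catchment_km2_range
    areas = rng.uniform(lo, hi, n_basins) * 1e6  # m2
    widths = np.array([_snap(math.sqrt(A / 2.0), cell) for A in areas])
    lengths = 2.0 * widths
    amps = config.meander_amplitude * rng.uniform(0.2, 1.8, n_basins)
    amps = np.minimum(amps, widths / 4.0)
    if config.meander_amplitude == 0:
        amps[:] = 0.0
    tree = rng.uniform(*config.tree_density_range, n_basins)
    base_elev = rng.uniform(120.0, 380.0, n_basins)
    share = np.clip(rng.normal(config.quickflow_share, 0.15, n_basins), 0.05, 0.8)
    gradient = config.valley_gradient * rng.uniform(0.3, 2.0, n_basins)

    tile_w = _snap(lengths.max() + 2 * _MARGIN, cell)
    tile_h = _snap(widths.max() + 2 * _MARGIN, cell)
    per_row = math.ceil(math.sqrt(n_basins))

    basins: list[BasinGeometry] = []
    reaches: dict[str, Reach] = {}
    sites_rows = []
    catchments: dict[str, Polygon] = {}
    site_no = 0
    for i in range(n_basins):
        col, row = i % per_row, i // per_row
        x0 = _snap(col * tile_w + _MARGIN, cell)
        y0 = _snap(row * tile_h + _MARGIN, cell)
        bg = BasinGeometry(
            basin_id=i,
            x0=x0,
            y0=y0,
            length=lengths[i],
            width=widths[i],
            amplitude=float(amps[i]),
            wavelength=config.meander_wavelength,
            tree_density=float(tree[i]),
            base_elev=float(base_elev[i]),
            quickflow_share=float(share[i]),
            gradient=float(gradient[i]),
        )
        basins.append(bg)

        # stem split into reaches at tributary junctions
        break_x = [x0] + [x0 + f * bg.length for f in _TRIB_FRACS] + [x0 + bg.length]
        for seg in range(len(break_x) - 1):
            xs = np.arange(break_x[seg], break_x[seg + 1] + cell / 2, cell)
            xs[-1] = break_x[seg + 1]
            verts = np.column_stack([xs, bg.stem_y(xs)])
            rid = f"b{i}_stem{seg}"
            down = f"b{i}_stem{seg + 1}" if seg < len(break_x) - 2 else None
            da = (break_x[seg + 1] - x0) * bg.width / 1e6
            reaches[rid] = Reach(rid, verts, da, down)
        for t, f in enumerate(_TRIB_FRACS):
            xj = x0 + f * bg.length
            y_edge = y0 if t % 2 == 0 else y0 + bg.width
            yj = float(bg.stem_y(xj)[()])
            rid = f"b{i}_trib{t}"
            reaches[rid] = Reach(
                rid,
                np.array([[xj, y_edge], [xj, yj]]),
                0.2 * (xj - x0) * bg.width / 1e6,
                f"b{i}_stem{t + 1}",
            )

        # sites on the stem; the most downstream site drains the whole basin
        n_here = min(spb, config.n_sites - site_no)
        fracs = [1.0 - 0.3 * j for j in range(n_here)][::-1]
        for f in fracs:
            xs = _snap(x0 + f * bg.length, cell)
            xs = min(xs, x0 + bg.length)
            sid = f"S{site_no + 1:03d}"
            ys = float(bg.stem_y(xs)[()])
            sites_rows.append({"site": sid, "x": xs, "y": ys, "basin": i})
            poly = box(x0, y0, xs, y0 + bg.width)
            if poly.area <= 0:
                raise ValueError(f"degenerate zero-area catchment for site {sid}")
            catchments[sid] = poly
            site_no += 1

    net = RiverNetwork(
        reaches=reaches,
        sites={r["site"]: (r["x"], r["y"]) for r in sites_rows},
    )
    net.validate()
    return net, pd.DataFrame(sites_rows), catchments, basins


# ---------------------------------------------------------------------------
# Terrain and land cover


_PATCH_CELLS = 8
_LC_BASE_ALPHA = {  # Dirichlet base for the seven dry-land categories
    "AGRI": 5.0, "ARTI": 1.2, "BROAD": 5.0, "HERBA": 4.0,
    "FORESTS": 1.6, "NEEDLE": 2.0, "OTHER": 1.2,
}


def generate_terrain_and_landcover(
    config: SimConfig,
    basins: list[BasinGeometry],
    rng: np.random.Generator,
) -> tuple[RasterGrid, RasterGrid]:
    """Surface model (terrain + riparian canopy) and land-cover raster.

    Terrain falls along the stem at ``valley_gradient`` and rises away from
    the channel at ``valley_cross_slope``, so elevation decreases
    monotonically along every flow path.  Riparian canopy blocks of height
    ``tree_height`` are placed within 50 m of the stem with per-basin
    probability ``tree_density`` (nested draws: raising the density only
    adds canopy).  Land cover is patch-wise multinomial from per-basin
    Dirichlet proportions, with canopy cells as forest and channel cells
    as water.
    """
    cell = config.cell_size
    per_row = math.ceil(math.sqrt(len(basins)))
    n_rows_b = math.ceil(len(basins) / per_row)
    tile_w = _snap(max(b.length for b in basins) + 2 * _MARGIN, cell)
    tile_h = _snap(max(b.width for b in basins) + 2 * _MARGIN, cell)
    ncols = int(round(per_row * tile_w / cell))
    nrows = int(round(n_rows_b * tile_h / cell))
    dem = np.zeros((nrows, ncols))
    lc = np.full((nrows, ncols), 4.0)  # herbaceous background
    xs = (np.arange(ncols) + 0.5) * cell
    ys = (nrows - np.arange(nrows) - 0.5) * cell
    X, Y = np.meshgrid(xs, ys)

    code_of = {name: code for code, name in
               zip(range(1, 9), ["AGRI", "ARTI", "BROAD", "HERBA", "FORESTS", "NEEDLE", "OTHER", "WATER"])}

    for bg in basins:
        c0 = int((bg.x0 - _MARGIN) // cell)
        c1 = int(math.ceil((bg.x0 + bg.length + _MARGIN) / cell))
        r_top = nrows - int(math.ceil((bg.y0 + bg.width + _MARGIN) / cell))
        r_bot = nrows - int((bg.y0 - _MARGIN) // cell)
        c0, r_top = max(c0, 0), max(r_top, 0)
        sl = np.s_[r_top:r_bot, c0:c1]
        Xw, Yw = X[sl], Y[sl]
        dist = np.abs(Yw - bg.stem_y(Xw))
        xc = np.clip(Xw, bg.x0, bg.x0 + bg.length)
        terrain = (
            bg.base_elev
            + bg.gradient * (bg.x0 + bg.length - xc)
            + config.valley_cross_slope * dist
        )
        # riparian canopy: nested Bernoulli blocks within the 50 m corridor
        strip = (dist > 0.6 * cell) & (dist <= 50.0) & (Xw >= bg.x0) & (Xw <= bg.x0 + bg.length)
        u = rng.uniform(size=Xw.shape)
        canopy = strip & (u < bg.tree_density)
        dem[sl] = terrain + config.tree_height * canopy

        # land cover patches from per-basin proportions
        probs = rng.dirichlet([_LC_BASE_ALPHA[k] for k in _LC_BASE_ALPHA])
        pr, pc = (r_bot - r_top) // _PATCH_CELLS + 1, (c1 - c0) // _PATCH_CELLS + 1
        patch_codes = rng.choice(
            [code_of[k] for k in _LC_BASE_ALPHA], size=(pr, pc), p=probs
        )
        full = np.kron(patch_codes, np.ones((_PATCH_CELLS, _PATCH_CELLS)))
        lc[sl] = full[: r_bot - r_top, : c1 - c0]
        needle = rng.uniform(size=Xw.shape) < 0.3
        lc[sl] = np.where(canopy, np.where(needle, code_of["NEEDLE"], code_of["BROAD"]), lc[sl])
        lc[sl] = np.where(dist <= 0.6 * cell, code_of["WATER"], lc[sl])

    dem_grid = RasterGrid(dem, 0.0, 0.0, cell)
    lc_grid = RasterGrid(lc, 0.0, 0.0, cell)
    return dem_grid, lc_grid


# ---------------------------------------------------------------------------
# Climate and discharge


def _dates(config: SimConfig) -> pd.DatetimeIndex:
    return pd.date_range(
        f"{config.start_year}-01-01",
        f"{config.start_year + config.n_years - 1}-12-31",
        freq="D",
    )


def generate_climate(
    config: SimConfig,
    site_elev: pd.Series,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Daily (T_aM, T_am) per site: seasonal sinusoid + regional AR(1)
    weather + scheduled additive heat waves + site offsets.

    Returns two DataFrames (dates x sites).  T_am <= T_aM every day.
    """
    dates = _dates(config)
    n = len(dates)
    doy = dates.dayofyear.to_numpy()
    seasonal = config.air_mean + config.air_seasonal_amp * np.cos(
        2 * math.pi * (doy - 201) / 365.25
    )
    rho, sd = config.air_ar1_rho, config.air_ar1_sd
    innov = rng.normal(0.0, sd * math.sqrt(max(1e-12, 1 - rho**2)), n)
    ar = np.empty(n)
    ar[0] = rng.normal(0.0, sd) if sd > 0 else 0.0
    for t in range(1, n):
        ar[t] = rho * ar[t - 1] + innov[t]
    if sd == 0:
        ar[:] = 0.0
    waves = np.zeros(n)
    for w in config.heat_waves:
        center = (pd.Timestamp(w.date) - dates[0]).days
        half = w.duration // 2
        for d in range(-half, half + 1):
            idx = center + d
            if 0 <= idx < n:
                waves[idx] += w.amplitude * (1.0 - abs(d) / (half + 1.0))
    regional = seasonal + ar + waves

    elev_anom = site_elev - site_elev.mean()
    ta_max = {}
    ta_min = {}
    for sid in site_elev.index:
        # zero weather noise means a deterministic pure-sinusoid climate
        if sd > 0:
            offset = -0.0065 * float(elev_anom[sid]) + rng.normal(0.0, 0.5)
            site_noise = rng.normal(0.0, 0.5, n)
        else:
            offset, site_noise = 0.0, np.zeros(n)
        tmax = regional + offset + site_noise
        rng_day = np.maximum(
            0.5, rng.normal(config.diurnal_range_mean, config.diurnal_range_sd, n)
        )
        ta_max[sid] = tmax
        ta_min[sid] = tmax - rng_day
    return (
        pd.DataFrame(ta_max, index=dates),
        pd.DataFrame(ta_min, index=dates),
    )


def generate_discharge(
    config: SimConfig,
    site_share: pd.Series,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Daily discharge and water level per site.

    Q = constant site baseflow + exponentially-recessed storm quickflow.
    ``site_share`` is each site's long-run quickflow fraction of total
    flow; storm timing is regional, amplitudes site-specific.  Level is
    the monotone stage relation level = k Q^0.4.  Returns (Q, level,
    baseflow per site).
    """
    dates = _dates(config)
    n = len(dates)
    storms = rng.uniform(size=n) < config.storm_rate
    decay = math.exp(-config.storm_decay)
    q = {}
    level = {}
    qbase = pd.Series(
        rng.lognormal(math.log(config.baseflow_median), config.baseflow_sigma, len(site_share)),
        index=site_share.index,
    )
    k_lo, k_hi = config.level_coef_range
    for sid in site_share.index:
        share = float(site_share[sid])
        ratio = share / (1.0 - share)
        mean_amp = ratio * float(qbase[sid]) * (1.0 - decay) / max(config.storm_rate, 1e-9)
        amps = np.where(storms, rng.exponential(mean_amp, n), 0.0)
        quick = np.empty(n)
        quick[0] = amps[0]
        for t in range(1, n):
            quick[t] = quick[t - 1] * decay + amps[t]
        qq = np.maximum(float(qbase[sid]) + quick, 1e-6)
        q[sid] = qq
        k = rng.uniform(k_lo, k_hi)
        level[sid] = k * qq**0.4
    return pd.DataFrame(q, index=dates), pd.DataFrame(level, index=dates), qbase


# ---------------------------------------------------------------------------
# Water temperature


def simulate_water_temperature(
    ta_max: pd.DataFrame,
    ta_min: pd.DataFrame,
    q: pd.DataFrame,
    event_params: pd.DataFrame,
    site_params: pd.DataFrame,
    extreme_dates,
    obs_sd: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Forward-Euler daily maximum water temperature per site.

    Within 7 days of an extreme date the site's event triple applies;
    elsewhere the site-level triple.  Optional Gaussian observation noise
    is added to the recorded series.  Raises on Euler instability.
    """
    dates = ta_max.index
    n = len(dates)
    out = {}
    ev_dates = [pd.Timestamp(d) for d in extreme_dates]
    for sid in ta_max.columns:
        a_t = np.full(n, float(site_params.loc[sid, "a"]))
        b_t = np.full(n, float(site_params.loc[sid, "b"]))
        c_t = np.full(n, float(site_params.loc[sid, "c"]))
        ev = event_params[event_params["site"] == sid]
        for _, row in ev.iterrows():
            center = (pd.Timestamp(row["date"]) - dates[0]).days
            lo = max(0, center - WINDOW_HALF)
            hi = min(n, center + WINDOW_HALF + 1)
            a_t[lo:hi], b_t[lo:hi], c_t[lo:hi] = row["a"], row["b"], row["c"]
        taM = ta_max[sid].to_numpy()
        tam = ta_min[sid].to_numpy()
        qq = q[sid].to_numpy()
        ab = a_t[0] + b_t[0]
        tw0 = (a_t[0] * taM[0] + b_t[0] * tam[0] + c_t[0] * qq[0]) / ab if ab > 0 else taM[0]
        tw = ThermalDynamicsModel.simulate(taM, tam, qq, a_t, b_t, c_t, tw0)
        if obs_sd > 0:
            tw = tw + rng.normal(0.0, obs_sd, n)
        out[sid] = tw
    return pd.DataFrame(out, index=dates)


# ---------------------------------------------------------------------------
# Orchestration


def _draw_params(
    config: SimConfig,
    covariates_z: pd.DataFrame,
    qbase: pd.Series,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, int, int]:
    """Site-level and per-event true triples from the linear link."""
    t = config.truth
    sites = covariates_z.index
    mean = {}
    for p in ("a", "b", "c"):
        mu = np.full(len(sites), t.intercepts[p])
        for cov, slope in t.slopes[p].items():
            mu = mu + slope * covariates_z[cov].to_numpy()
        mean[p] = mu
    n_floored = 0
    n_redraw = 0
    rows = []
    for i, sid in enumerate(sites):
        qmin = float(qbase[sid])
        for attempt in range(100):
            a = mean["a"][i] + (rng.normal(0, t.coef_sd) if t.coef_sd > 0 else 0.0)
            b = mean["b"][i] + (rng.normal(0, t.coef_sd) if t.coef_sd > 0 else 0.0)
            c = mean["c"][i] + (rng.normal(0, t.coef_sd) if t.coef_sd > 0 else 0.0)
            if (a + b) / qmin <= 1.8:
                break
            n_redraw += 1
        if a < t.ab_floor or b < t.ab_floor:
            n_floored += 1
            a, b = max(a, t.ab_floor), max(b, t.ab_floor)
        rows.append({"site": sid, "a": a, "b": b, "c": c})
    site_params = pd.DataFrame(rows).set_index("site")

    ev_rows = []
    for sid in sites:
        for d in (w.date for w in config.heat_waves):
            a, b, c = site_params.loc[sid, ["a", "b", "c"]]
            if t.event_mode == "jitter" and t.event_jitter_sd > 0:
                qmin = float(qbase[sid])
                for attempt in range(100):
                    aa = a + rng.normal(0, t.event_jitter_sd)
                    bb = b + rng.normal(0, t.event_jitter_sd)
                    cc = c + rng.normal(0, t.event_jitter_sd)
                    if (aa + bb) / qmin <= 1.8:
                        break
                a, b, c = max(aa, t.ab_floor), max(bb, t.ab_floor), cc
            ev_rows.append({"site": sid, "date": d, "a": a, "b": b, "c": c})
    return site_params, pd.DataFrame(ev_rows), n_floored, n_redraw


def make_dataset(config: SimConfig | None = None, seed: int | None = None) -> SyntheticStudy:
    """Generate the full synthetic study, reproducibly from (config, seed).

    Order: network and catchments -> terrain and land cover -> climate ->
    discharge -> measured landscape covariates at the catchment scale ->
    true (a, b, c) from the standardized covariates -> water temperature.
    """
    config = config or SimConfig()
    if seed is not None:
        config.seed = seed
    config.validate()
    rng = np.random.default_rng(config.seed)

    net, sites, catchments, basins = generate_network(config, rng)
    dem, lc = generate_terrain_and_landcover(config, basins, rng)

    site_elev = pd.Series(
        {r["site"]: dem.value_at(r["x"], r["y"]) for r in sites.to_dict("records")}
    )
    ta_max, ta_min = generate_climate(config, site_elev, rng)
    share = pd.Series(
        {r["site"]: basins[r["basin"]].quickflow_share for r in sites.to_dict("records")}
    )
    q, level, qbase = generate_discharge(config, share, rng)

    # partial series (no water temperature yet) for covariate measurement
    series: dict[str, DailySiteSeries] = {}
    for sid in sites["site"]:
        df = pd.DataFrame(
            {
                "ta_max": ta_max[sid],
                "ta_min": ta_min[sid],
                "tw_max": np.nan,
                "q": q[sid],
                "level": level[sid],
            }
        )
        series[sid] = DailySiteSeries(sid, df)

    event_dates = [w.date for w in config.heat_waves]
    land = assemble_landscape_table(
        dem, lc, net, catchments, series, event_dates,
        latitude_deg=config.latitude_deg,
    )
    cov = (
        land[land["scale"] == "CA"]
        .set_index("site")[PREDICTOR_ORDER]
        .loc[sites["site"]]
    )
    sd = cov.std(ddof=1)
    sd = sd.replace(0.0, 1.0)  # constant covariates carry no link signal
    cov_z = (cov - cov.mean()) / sd

    site_params, event_params, n_floored, n_redraw = _draw_params(config, cov_z, qbase, rng)
    tw = simulate_water_temperature(
        ta_max, ta_min, q, event_params, site_params, event_dates, config.obs_sd, rng
    )
    for sid in sites["site"]:
        series[sid].data["tw_max"] = tw[sid]
        series[sid].validate()

    truth = SyntheticTruth(
        covariates=cov,
        covariates_z=cov_z,
        params=site_params,
        event_params=event_params,
        extreme_dates=event_dates,
        bfi_target=1.0 - share,
        n_floored=n_floored,
        n_stability_redraws=n_redraw,
    )
    truth.validate()
    return SyntheticStudy(
        config=config,
        network=net,
        sites=sites,
        catchments=catchments,
        basins=basins,
        dem=dem,
        landcover=lc,
        series=series,
        truth=truth,
    )


# ---------------------------------------------------------------------------
# Light-weight regression tables (for selection studies)


def make_regression_table(
    n_sites: int = 92,
    active: dict[str, float] | None = None,
    noise_sd: float = 0.5,
    predictors: list[str] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Standardized predictor table with a known sparse linear response.

    Independent standard-normal predictors (the full 15-variable set by
    default); the response ``y`` is the given active effects plus Gaussian
    noise.  Returns (table with y + predictors, true effects).
    """
    rng = np.random.default_rng(seed)
    predictors = predictors or PREDICTOR_ORDER
    active = active if active is not None else {"SHADE": -0.4, "AREA": 0.5, "BFI": -0.35}
    X = pd.DataFrame(
        rng.standard_normal((n_sites, len(predictors))), columns=predictors
    )
    y = np.zeros(n_sites)
    for name, beta in active.items():
        y = y + beta * X[name].to_numpy()
    y = y + rng.normal(0.0, noise_sd, n_sites)
    table = X.copy()
    table.insert(0, "y", y)
    return table, dict(active)
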