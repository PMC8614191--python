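"""Study configuration for the synthetic generator and the pipeline.

Defaults mirror the study design the analysis targets: 92 measurement
sites observed daily over 2012-2018, with 17 summer heat waves injected on
the published extreme dates.  All lengths are meters, areas km2 at the
interface, temperatures degC, discharge m3/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["HeatWave", "CoefficientTruth", "SimConfig", "PipelineConfig"]


@dataclass
class HeatWave:
    """One scheduled air-temperature anomaly: peak ``date`` (ISO string),
    additive ``amplitude`` (degC) and total ``duration`` in days (odd,
    centered on the date)."""

    date: str
    amplitude: float = 8.0
    duration: int = 3


#: Order of the 15 environmental predictors (the report's column order).
PREDICTOR_ORDER = [
    "SHADE", "SINUO", "AGRI", "ARTI", "BROAD", "HERBA", "FORESTS",
    "NEEDLE", "OTHER", "WATER", "AREA", "SLOP", "LEVEL", "ELEV", "BFI",
]


@dataclass
class CoefficientTruth:
    """Linear link from standardized landscape covariates to the thermal
    parameters: param = intercept + sum(slope * z(covariate)) + N(0, sd).

    Slopes are response units per 1 sd of the covariate.  Day and night
    sensitivities are floored at ``ab_floor`` (convective coefficients are
    physically non-negative); floored sites are counted in the truth record.
    """

    intercepts: dict[str, float] = field(
        default_factory=lambda: {"a": 0.55, "b": 0.4, "c": 0.1}
    )
    slopes: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "a": {"SHADE": -0.15, "AREA": 0.18, "LEVEL": 0.15},
            "b": {"BFI": -0.18, "OTHER": 0.15, "NEEDLE": 0.12},
            "c": {"OTHER": 0.12, "SINUO": 0.1, "AREA": -0.08},
        }
    )
    coef_sd: float = 0.06
    #: "jitter" redraws the site-level noise per event; "constant" keeps one
    #: triple per site for all events.
    event_mode: str = "constant"
    event_jitter_sd: float = 0.05
    ab_floor: float = 0.02


#: The 17 published summer extreme dates double as the default wave schedule.
from .extremes import STUDY_SUMMER_EVENT_DATES as DEFAULT_SUMMER_WAVES  # noqa: E402


@dataclass
class SimConfig:
    """Synthetic-study configuration.

    The defaults are the study conditions: n_sites=92, 7 years (2012-2018),
    latitude 50 N (Wallonia), 17 summer waves of +8 degC.
    """

    n_sites: int = 92
    start_year: int = 2012
    n_years: int = 7
    seed: int = 0
    latitude_deg: float = 50.0
    heat_waves: list[HeatWave] = field(
        default_factory=lambda: [HeatWave(d) for d in DEFAULT_SUMMER_WAVES]
    )
    truth: CoefficientTruth = field(default_factory=CoefficientTruth)

    # climate / hydrology
    air_mean: float = 10.0          # annual mean of T_aM (degC)
    air_seasonal_amp: float = 10.0  # seasonal half-range of the sinusoid
    diurnal_range_mean: float = 9.0  # mean T_aM - T_am
    diurnal_range_sd: float = 1.5
    air_ar1_sd: float = 2.0         # sd of the AR(1) weather noise (degC)
    air_ar1_rho: float = 0.7
    obs_sd: float = 0.2             # water-temperature observation noise (degC)
    baseflow_median: float = 2.0    # lognormal median of site baseflow (m3/s)
    baseflow_sigma: float = 0.25
    quickflow_share: float = 0.4    # mean quickflow / total flow ratio
    storm_rate: float = 0.08        # storm pulses per day
    storm_decay: float = 0.25       # recession rate (1/day)
    level_coef_range: tuple[float, float] = (0.15, 0.35)  # level = k * Q**0.4

    # terrain / land cover / network
    cell_size: float = 10.0         # raster resolution (m)
    catchment_km2_range: tuple[float, float] = (2.0, 12.0)
    sites_per_basin: int = 1
    meander_amplitude: float = 120.0  # stem meander amplitude (m); 0 = straight
    meander_wavelength: float = 800.0
    tree_density_range: tuple[float, float] = (0.1, 0.9)  # riparian canopy cover
    tree_height: float = 22.0       # canopy height added to the surface model (m)
    valley_gradient: float = 0.004  # along-channel elevation gradient (m/m)
    valley_cross_slope: float = 0.02  # valley side slope away from the channel (m/m)

    def validate(self) -> None:
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")
        if self.n_years < 1:
            raise ValueError("n_years must be >= 1")
        for sd_name in ("air_ar1_sd", "obs_sd"):
            if getattr(self, sd_name) < 0:
                raise ValueError(f"{sd_name} must be >= 0")
        if self.truth.coef_sd < 0:
            raise ValueError("coef_sd must be >= 0")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        lo, hi = self.catchment_km2_range
        if lo <= 0 or hi < lo:
            raise ValueError("catchment_km2_range must be positive and ordered")
        start = f"{self.start_year}-01-01"
        end = f"{self.start_year + self.n_years - 1}-12-31"
        for w in self.heat_waves:
            if not (start <= w.date <= end):
                raise ValueError(f"heat wave {w.date} outside simulated period {start}..{end}")
        if self.truth.event_mode not in ("constant", "jitter"):
            raise ValueError("truth.event_mode must be 'constant' or 'jitter'")
        # stability guard for the daily Euler step: (a+b)/Q must stay below 2
        # or the generated trajectory oscillates.  This checks the bulk of
        # the coefficient/baseflow distributions (2 sd); the generator
        # additionally redraws individual site tails that violate the bound.
        t = self.truth
        spread = (
            sum(v**2 for v in t.slopes["a"].values())
            + sum(v**2 for v in t.slopes["b"].values())
            + 2.0 * t.coef_sd**2
        ) ** 0.5
        typical_ab = t.intercepts["a"] + t.intercepts["b"] + 2.0 * spread
        q_floor = self.baseflow_median * math.exp(-2.0 * self.baseflow_sigma)
        if typical_ab / q_floor > 2.0:
            raise ValueError(
                f"unstable configuration: typical (a+b)/Q ~ {typical_ab / q_floor:.2f} > 2; "
                "lower the thermal-sensitivity truth or raise the baseflow"
            )


@dataclass
class PipelineConfig:
    """End-to-end pipeline options (defaults match the study conventions)."""

    out_dir: Path = Path("streamtherm_out")
    seed: int = 0
    buffer_radii_m: tuple[float, float] = (1000.0, 2000.0)
    corridor_halfwidth_m: float = 50.0
    bfi_block_days: int = 5
    bfi_turning_factor: float = 0.9
    extreme_quantile: float = 0.98
    extreme_site_fraction: float = 0.5
    channel_slope_distance_m: float = 4000.0
    cast_shadows: bool = True
    fit_mode: str = "derivative"
    sim: SimConfig = field(default_factory=SimConfig)

    def validate(self) -> None:
        if any(r <= 0 for r in self.buffer_radii_m):
            raise ValueError("buffer radii must be positive")
        if self.corridor_halfwidth_m <= 0:
            raise ValueError("corridor half-width must be positive")
        if self.bfi_block_days < 2:
            raise ValueError("BFI block length must be >= 2 days")
        if not (0 < self.bfi_turning_factor < 1):
            raise ValueError("BFI turning factor must lie in (0, 1)")
        if not (0.5 < self.extreme_quantile < 1):
            raise ValueError("extreme quantile must lie in (0.5, 1)")
        if not (0 <= self.extreme_site_fraction <= 1):
            raise ValueError("site fraction must lie in [0, 1]")
        if self.fit_mode not in ("derivative", "trajectory"):
            raise ValueError("fit_mode must be 'derivative' or 'trajectory'")
        self.sim.validate()


def _update_dataclass(obj, values: dict) -> None:
    for key, val in values.items():
        if not hasattr(obj, key):
            raise ValueError(f"unknown config key '{key}' for {type(obj).__name__}")
        cur = getattr(obj, key)
        if key == "heat_waves":
            setattr(obj, key, [HeatWave(**w) if isinstance(w, dict) else HeatWave(w) for w in val])
        elif hasattr(cur, "__dataclass_fields__") and isinstance(val, dict):
            _update_dataclass(cur, val)
        elif isinstance(cur, tuple) and isinstance(val, (list, tuple)):
            setattr(obj, key, tuple(val))
        elif isinstance(cur, Path):
            setattr(obj, key, Path(val))
        else:
            setattr(obj, key, val)


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline config; missing keys keep their defaults."""
    values = yaml.safe_load(Path(path).read_text()) or {}
    cfg = PipelineConfig()
    _update_dataclass(cfg, values)
    cfg.validate()
    return cfg
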