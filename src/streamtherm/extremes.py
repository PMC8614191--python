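"""Extreme-date identification from water-temperature series.

Extreme events are dates on which daily maximum water temperature lies
outside its seasonal range across much of the monitoring network.  The
seasonal expectation is a cyclic penalized B-spline (P-spline) on
day-of-year with GCV-chosen smoothing; a date qualifies as extreme when
its residual exceeds the site's high quantile at a sufficient fraction of
sites, and consecutive qualifying days collapse to the peak day.

This anomaly rule is a documented stand-in for the GAM-based procedure of
the companion monitoring study; an externally supplied event list can
bypass detection entirely (see the pipeline's ``events`` input).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline

from .series import DailySiteSeries

__all__ = [
    "ExtremeDate",
    "SeasonalBaseline",
    "fit_seasonal_baseline",
    "detect_extremes",
    "assign_season",
    "STUDY_SUMMER_EVENT_DATES",
]

#: The 17 summer extreme dates of the 2012-2018 Walloon monitoring record.
STUDY_SUMMER_EVENT_DATES = [
    "2012-08-19", "2013-07-22", "2014-06-09", "2014-07-17", "2014-07-24",
    "2014-08-07", "2015-06-05", "2015-07-04", "2015-07-17", "2015-07-27",
    "2015-08-13", "2016-08-27", "2017-07-07", "2017-08-30", "2018-07-01",
    "2018-07-27", "2018-08-23",
]

_SEASONS = {
    12: "winter", 1: "winter", 2: "winter",
    3: "spring", 4: "spring", 5: "spring",
    6: "summer", 7: "summer", 8: "summer",
    9: "autumn", 10: "autumn", 11: "autumn",
}

PERIOD = 365.25


def assign_season(date) -> str:
    """Meteorological season: Dec-Feb winter, Mar-May spring, Jun-Aug
    summer, Sep-Nov autumn."""
    return _SEASONS[pd.Timestamp(date).month]


@dataclass
class ExtremeDate:
    date: pd.Timestamp
    season: str
    anomaly: float        # network-mean residual on the day (degC)
    site_fraction: float  # fraction of sites exceeding their threshold

    def __post_init__(self) -> None:
        if not (0.0 <= self.site_fraction <= 1.0):
            raise ValueError("site fraction must lie in [0, 1]")
        if self.season != assign_season(self.date):
            raise ValueError("season inconsistent with the month rule")


class SeasonalBaseline:
    """Cyclic P-spline expectation of daily max water temperature.

    ``n_basis`` cubic B-splines wrap around the year; the coefficient
    second-difference penalty (also wrapped) is tuned by generalized
    cross-validation over a log-spaced grid.
    """

    def __init__(self, n_basis: int = 12, degree: int = 3):
        self.n_basis = n_basis
        self.degree = degree
        self.coef_: np.ndarray | None = None
        self.lambda_: float | None = None

    def _basis(self, doy: np.ndarray) -> np.ndarray:
        nb, k = self.n_basis, self.degree
        h = PERIOD / nb
        knots = (np.arange(-k, nb + k + 1)) * h
        B = BSpline.design_matrix(np.mod(doy, PERIOD), knots, k).toarray()
        # wrap the overhanging columns to make the basis periodic
        C = np.zeros((len(doy), nb))
        for j in range(B.shape[1]):
            C[:, j % nb] += B[:, j]
        return C

    def _penalty(self) -> np.ndarray:
        nb = self.n_basis
        D = np.zeros((nb, nb))
        for j in range(nb):
            D[j, j] += 1.0
            D[j, (j + 1) % nb] += -2.0
            D[j, (j + 2) % nb] += 1.0
        return D.T @ D

    def fit(self, doy: np.ndarray, values: np.ndarray) -> "SeasonalBaseline":
        B = self._basis(np.asarray(doy, float))
        y = np.asarray(values, float)
        BtB = B.T @ B
        Bty = B.T @ y
        P = self._penalty()
        n = len(y)
        best = (np.inf, None, None)
        for lam in np.logspace(-2, 6, 25):
            A = BtB + lam * P
            coef = np.linalg.solve(A, Bty)
            edf = float(np.trace(np.linalg.solve(A, BtB)))
            rss = float(np.sum((y - B @ coef) ** 2))
            gcv = n * rss / (n - edf) ** 2
            if gcv < best[0]:
                best = (gcv, coef, lam)
        self.coef_, self.lambda_ = best[1], best[2]
        return self

    def predict(self, doy) -> np.ndarray:
        if self.coef_ is None:
            raise RuntimeError("baseline not fitted")
        return self._basis(np.atleast_1d(np.asarray(doy, float))) @ self.coef_


def _fractional_doy(index: pd.DatetimeIndex) -> np.ndarray:
    """Day-of-year mapped onto [0, PERIOD) so leap years align."""
    doy = index.dayofyear.to_numpy().astype(float)
    year_len = np.where(index.is_leap_year, 366.0, 365.0)
    return (doy - 1.0) * PERIOD / year_len


def fit_seasonal_baseline(series: DailySiteSeries) -> pd.Series:
    """Residuals (observed - cyclic seasonal expectation) of tw_max.

    Requires at least one full year of data.
    """
    data = series.data["tw_max"].dropna()
    if len(data) < 365:
        raise ValueError(
            f"site {series.site_id}: need >= 1 year of data, have {len(data)} days"
        )
    doy = _fractional_doy(data.index)
    baseline = SeasonalBaseline().fit(doy, data.to_numpy())
    resid = data.to_numpy() - baseline.predict(doy)
    return pd.Series(resid, index=data.index, name=series.site_id)


def detect_extremes(
    residuals: pd.DataFrame,
    quantile: float = 0.98,
    site_fraction: float = 0.5,
) -> list[ExtremeDate]:
    """Region-wide extreme dates from per-site residuals (dates x sites).

    A day qualifies when the residual exceeds the site's ``quantile``
    threshold at at least ``site_fraction`` of reporting sites (and at
    least one site).  Runs of consecutive qualifying days collapse to the
    day with the largest network-mean residual.
    """
    if not (0.5 < quantile < 1.0):
        raise ValueError("quantile must lie in (0.5, 1)")
    if not (0.0 <= site_fraction <= 1.0):
        raise ValueError("site_fraction must lie in [0, 1]")
    thresholds = residuals.quantile(quantile)
    exceed = residuals.gt(thresholds, axis=1)
    n_reporting = residuals.notna().sum(axis=1)
    frac = exceed.sum(axis=1) / n_reporting.replace(0, np.nan)
    qualifying = (frac >= site_fraction) & (exceed.sum(axis=1) > 0)
    mean_resid = residuals.mean(axis=1)

    out: list[ExtremeDate] = []
    run: list[pd.Timestamp] = []
    q_dates = residuals.index[qualifying]
    for i, d in enumerate(q_dates):
        run.append(d)
        last = i == len(q_dates) - 1
        if last or (q_dates[i + 1] - d).days > 1:
            peak = max(run, key=lambda x: mean_resid.loc[x])
            out.append(
                ExtremeDate(
                    date=peak,
                    season=assign_season(peak),
                    anomaly=float(mean_resid.loc[peak]),
                    site_fraction=float(frac.loc[peak]),
                )
            )
            run = []
    return out


def residual_table(series_map: dict[str, DailySiteSeries]) -> pd.DataFrame:
    """Seasonal-baseline residuals for every site, aligned on dates."""
    return pd.DataFrame({sid: fit_seasonal_baseline(s) for sid, s in series_map.items()})
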