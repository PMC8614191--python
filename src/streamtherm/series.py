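"""Daily per-site climate/hydrology/temperature records.

The canonical on-disk form is one CSV per site with columns
``date, ta_max, ta_min, tw_max, q, level`` (ISO dates, degC, flow in m3/s,
level in m).  Dates must be contiguous; missing observations are explicit
NaN cells, never absent rows.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["DailySiteSeries", "read_series_csv", "write_series_csv", "SeriesSchemaError"]

SERIES_COLUMNS = ["date", "ta_max", "ta_min", "tw_max", "q", "level"]


class SeriesSchemaError(ValueError):
    """A series CSV violates the documented schema."""


@dataclass
class DailySiteSeries:
    """Daily record for one measurement site.

    ``data`` is a DataFrame indexed by a contiguous daily DatetimeIndex with
    float columns ta_max, ta_min, tw_max, q, level.  Invariants (checked by
    :meth:`validate`): contiguous dates, ta_min <= ta_max, q > 0 where
    observed.
    """

    site_id: str
    data: pd.DataFrame

    def validate(self) -> None:
        idx = self.data.index
        if not isinstance(idx, pd.DatetimeIndex):
            raise SeriesSchemaError(f"site {self.site_id}: index must be dates")
        if len(idx) > 1:
            deltas = np.diff(idx.values).astype("timedelta64[D]").astype(int)
            if (deltas != 1).any():
                gaps = idx[:-1][deltas != 1]
                gap_desc = ", ".join(
                    f"after {d.date()} ({g - 1} missing day(s))"
                    for d, g in zip(gaps, deltas[deltas != 1])
                )
                raise SeriesSchemaError(f"site {self.site_id}: non-contiguous dates: {gap_desc}")
        for col in ("ta_max", "ta_min", "tw_max", "q", "level"):
            if col not in self.data.columns:
                raise SeriesSchemaError(f"site {self.site_id}: missing column '{col}'")
        both = self.data[["ta_min", "ta_max"]].dropna()
        if (both["ta_min"] > both["ta_max"] + 1e-9).any():
            bad = both.index[both["ta_min"] > both["ta_max"] + 1e-9][0]
            raise SeriesSchemaError(f"site {self.site_id}: ta_min > ta_max on {bad.date()}")
        q = self.data["q"].dropna()
        if (q <= 0).any():
            bad = q.index[q <= 0][0]
            raise SeriesSchemaError(f"site {self.site_id}: non-positive discharge on {bad.date()}")

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.data.index

    def __len__(self) -> int:
        return len(self.data)


def read_series_csv(path: str | Path, site_id: str | None = None) -> DailySiteSeries:
    """Read and validate one site's series CSV.

    The site id defaults to the file stem.  Schema violations raise
    :class:`SeriesSchemaError` naming the offending column or dates.
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in SERIES_COLUMNS if c not in df.columns]
    if missing:
        raise SeriesSchemaError(f"{path.name}: missing column(s) {missing}")
    df["date"] = pd.to_datetime(df["date"])
    df = df.set_index("date")[["ta_max", "ta_min", "tw_max", "q", "level"]].astype(float)
    s = DailySiteSeries(site_id=site_id or path.stem, data=df)
    s.validate()
    return s


def write_series_csv(series: DailySiteSeries, path: str | Path) -> None:
    df = series.data.copy()
    df.insert(0, "date", df.index.strftime("%Y-%m-%d"))
    df.to_csv(path, index=False, float_format="%.6g")


def read_series_dir(path: str | Path) -> dict[str, DailySiteSeries]:
    """Read every ``*.csv`` in a directory as one site series each."""
    out: dict[str, DailySiteSeries] = {}
    for f in sorted(Path(path).glob("*.csv")):
        s = read_series_csv(f)
        out[s.site_id] = s
    return out
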