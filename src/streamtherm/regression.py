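"""Stepwise-AIC multiple linear regression of thermal parameters on
standardized environmental predictors.

For each of the three thermal parameters (a, b, c) and each of the six
spatial scales, a multiple linear regression is reduced by bidirectional
stepwise selection on AIC starting from the full 15-predictor model.  The
final refit reports estimates, two-sided t-test p-values with conventional
star codes, and adjusted R-squared.  p-values are not adjusted for
multiplicity (significance is conventionally read at 0.05).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import PREDICTOR_ORDER
from .landscape import SCALES

__all__ = [
    "standardize",
    "star_code",
    "StepwiseLinearModel",
    "StepwiseResults",
    "run_all_models",
    "build_report",
    "load_supplementary_tables",
]

log = logging.getLogger(__name__)

RESPONSES = ["a", "b", "c"]


def standardize(table: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Z-score the given columns (all numeric by default) to zero mean and
    unit sample variance.  Constant columns are rejected by name."""
    out = table.copy()
    cols = list(columns) if columns is not None else list(out.select_dtypes("number").columns)
    if len(out) < 3:
        raise ValueError("standardization needs at least 3 rows")
    for col in cols:
        sd = out[col].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"cannot standardize constant column '{col}'")
        out[col] = (out[col] - out[col].mean()) / sd
    return out


def star_code(p_value: float) -> str:
    """Conventional significance stars: *** <=0.001, ** <=0.01, * <=0.05,
    # <=0.1, blank above."""
    if not (0.0 <= p_value <= 1.0):
        raise ValueError(f"p-value {p_value} outside [0, 1]")
    if p_value <= 0.001:
        return "***"
    if p_value <= 0.01:
        return "**"
    if p_value <= 0.05:
        return "*"
    if p_value <= 0.1:
        return "#"
    return ""


@dataclass
class StepwiseResults:
    """Selection outcome and final OLS refit for one response x scale."""

    response: str
    scale: str | None
    selected: list[str]
    params: pd.Series          # estimates of the selected predictors (+ const)
    pvalues: pd.Series
    bse: pd.Series
    adj_rsquared: float
    aic: float
    aic_trace: list[tuple[str, float]] = field(default_factory=list)  # (move, AIC)

    @property
    def stars(self) -> pd.Series:
        return self.pvalues.map(star_code)

    def summary(self) -> str:
        lines = [
            f"Stepwise MLR: response {self.response}"
            + (f", scale {self.scale}" if self.scale else ""),
            f"  selected {len(self.selected)} of the candidate predictors; "
            f"Adj. R2 = {100 * self.adj_rsquared:.1f}%  AIC = {self.aic:.2f}",
            f"  {'predictor':<12}{'estimate':>10}{'std err':>10}{'p':>9}  sig",
        ]
        for name in self.selected:
            lines.append(
                f"  {name:<12}{self.params[name]:>10.3f}{self.bse[name]:>10.3f}"
                f"{self.pvalues[name]:>9.4f}  {self.stars[name]}"
            )
        lines.append("  note: p-values are unadjusted for multiplicity")
        return "\n".join(lines)


class StepwiseLinearModel:
    """Bidirectional stepwise-AIC linear model.

    Starts from the full model; at each step the single add or drop move
    with the lowest AIC is taken, stopping when no move lowers AIC.  Ties
    break by the fixed predictor order.  ``fit()`` returns
    :class:`StepwiseResults` from an OLS refit on the selected set.
    """

    def __init__(
        self,
        y: pd.Series,
        X: pd.DataFrame,
        response_name: str = "y",
        scale: str | None = None,
    ):
        if len(y) != len(X):
            raise ValueError("response and predictors differ in length")
        if len(y) <= X.shape[1] + 1:
            raise ValueError("need n > p + 1 observations for the full model")
        self.y = np.asarray(y, float)
        self.X = X
        self.names = list(X.columns)
        self.response_name = response_name
        self.scale = scale

    def _aic(self, cols: list[str]) -> float:
        """Gaussian AIC, -2 llf + 2 (p + 1), with the residual sum of
        squares floored at numerical noise (so exact fits tie rather than
        ranking by rounding error)."""
        X = sm.add_constant(self.X[cols], has_constant="add") if cols else np.ones((len(self.y), 1))
        n = len(self.y)
        ssr = float(sm.OLS(self.y, X).fit().ssr)
        floor = n * float(np.var(self.y)) * 1e-12
        ssr = max(ssr, floor, 1e-300)
        k = len(cols) + 1
        return n * math.log(2.0 * math.pi * ssr / n) + n + 2.0 * k

    def fit(self) -> StepwiseResults:
        current = list(self.names)
        cur_aic = self._aic(current)
        trace = [("start(full)", cur_aic)]
        while True:
            moves: list[tuple[float, int, str, list[str]]] = []
            for i, name in enumerate(self.names):
                if name in current:
                    cand = [c for c in current if c != name]
                    moves.append((self._aic(cand), i, f"-{name}", cand))
                else:
                    cand = [c for c in self.names if c in current or c == name]
                    moves.append((self._aic(cand), i, f"+{name}", cand))
            moves.sort(key=lambda m: (m[0], m[1]))
            best_aic, _, move, cand = moves[0]
            if best_aic < cur_aic - 1e-10:
                current, cur_aic = cand, best_aic
                trace.append((move, cur_aic))
                continue
            # no strict improvement: prefer parsimony on exact AIC ties
            # (degenerate perfect fits give -inf AIC for every superset)
            tie_drops = [
                m for m in moves if m[2].startswith("-") and m[0] <= cur_aic + 1e-10
            ]
            if tie_drops:
                best_aic, _, move, cand = tie_drops[0]
                current, cur_aic = cand, best_aic
                trace.append((move, cur_aic))
            else:
                break
        selected = [n for n in self.names if n in current]
        res = sm.OLS(
            self.y,
            sm.add_constant(self.X[selected], has_constant="add")
            if selected
            else np.ones((len(self.y), 1)),
        ).fit()
        params = res.params if selected else pd.Series({"const": float(res.params[0])})
        pvals = res.pvalues if selected else pd.Series({"const": float(res.pvalues[0])})
        bse = res.bse if selected else pd.Series({"const": float(res.bse[0])})
        return StepwiseResults(
            response=self.response_name,
            scale=self.scale,
            selected=selected,
            params=pd.Series(params),
            pvalues=pd.Series(pvals),
            bse=pd.Series(bse),
            adj_rsquared=float(res.rsquared_adj) if selected else 0.0,
            aic=cur_aic,
            aic_trace=trace,
        )


def run_all_models(
    tables: dict[str, pd.DataFrame],
    predictors: list[str] | None = None,
    responses: list[str] | None = None,
) -> list[StepwiseResults]:
    """Fit the stepwise model for every response x scale.

    ``tables`` maps scale -> per-site table holding both the (already
    standardized or raw) predictors and the response columns; predictors
    are standardized here, responses are left on their own scale.  Rows
    with any missing value in the model's columns are dropped listwise
    (logged).
    """
    predictors = predictors or PREDICTOR_ORDER
    responses = responses or RESPONSES
    out = []
    for scale, table in tables.items():
        for resp in responses:
            cols = [resp] + [p for p in predictors if p in table.columns]
            sub = table[cols].dropna()
            dropped = len(table) - len(sub)
            if dropped:
                log.info("scale %s response %s: %d rows dropped listwise", scale, resp, dropped)
            Xz = standardize(sub[cols[1:]])
            model = StepwiseLinearModel(sub[resp], Xz, response_name=resp, scale=scale)
            res = model.fit()
            for move, aic in res.aic_trace:
                log.debug("stepwise %s/%s: %s -> AIC %.2f", resp, scale, move, aic)
            out.append(res)
    return out


def build_report(results: list[StepwiseResults]) -> pd.DataFrame:
    """Matrix rendering of the stepwise fits: one row per response x scale,
    one column per predictor (estimate plus star code when selected, blank
    otherwise) and a final Adj. R2 (%) column."""
    rows = []
    order = {r: i for i, r in enumerate(RESPONSES)}
    scale_order = {s: i for i, s in enumerate(SCALES)}
    for res in sorted(
        results, key=lambda r: (order.get(r.response, 99), scale_order.get(r.scale or "", 99))
    ):
        row: dict[str, object] = {"response": res.response, "scale": res.scale}
        for name in PREDICTOR_ORDER:
            if name in res.selected:
                row[name] = f"{res.params[name]:.2f}{res.stars[name]}"
            else:
                row[name] = ""
        row["Adj. R2 (%)"] = round(100 * res.adj_rsquared, 1)
        rows.append(row)
    return pd.DataFrame(rows)


def load_supplementary_tables(directory: str | Path) -> dict[str, pd.DataFrame]:
    """Adapter for the study's six deposited per-scale CSVs.

    Each file holds the standardized model parameters (3) and environmental
    variables (15) for the 92 sites at one spatial scale.  Column names are
    matched case-insensitively onto the canonical predictor/response names;
    files are located by the scale tokens in their names (ca, ripa, buff_1,
    buff_2, buff_1_ripa, buff_2_ripa or the deposit's "Dataset N" order).
    """
    directory = Path(directory)
    files = sorted(directory.glob("*.csv"))
    if not files:
        raise FileNotFoundError(f"no supplementary CSVs found under {directory}")
    dataset_order = {  # deposit order of Dataset 1..6
        "1": "buff_1", "2": "buff_2", "3": "CA",
        "4": "buff_1_ripa", "5": "buff_2_ripa", "6": "ripa",
    }
    alias = {s.lower(): s for s in SCALES}
    out: dict[str, pd.DataFrame] = {}
    for f in files:
        stem = f.stem.lower()
        scale = None
        for key in sorted(alias, key=len, reverse=True):
            if key in stem:
                scale = alias[key]
                break
        if scale is None:
            digits = [ch for ch in stem if ch.isdigit()]
            if digits and digits[-1] in dataset_order:
                scale = dataset_order[digits[-1]]
        if scale is None:
            raise ValueError(f"cannot infer spatial scale from file name '{f.name}'")
        df = pd.read_csv(f)
        rename = {}
        canon = {n.lower(): n for n in PREDICTOR_ORDER + RESPONSES}
        for col in df.columns:
            key = col.strip().lower()
            if key in canon:
                rename[col] = canon[key]
        df = df.rename(columns=rename)
        missing = [c for c in RESPONSES if c not in df.columns]
        if missing:
            raise ValueError(f"{f.name}: missing response column(s) {missing}")
        out[scale] = df
    return out
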