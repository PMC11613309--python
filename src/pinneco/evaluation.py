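"""Evaluation metrics and post hoc variable-importance analysis.

Accuracy is mean absolute error; rank/level agreement is summarised by a
"quantile association" pair: empirical quantiles of prediction vs.
observation at decile midpoints (level agreement, separating bias from rank
skill) plus the Spearman rank correlation (monotone-invariant rank skill).

Variable importance is the individual conditional expectation (ICE): one
explanatory variable is varied over a predefined grid while all others stay
at their observed values, and predictions are averaged within four seasonal
2-week windows (early March, June, September and December), yielding one
partial-dependence-style curve per season.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

SEASON_WINDOWS = {"spring": 3, "summer": 6, "autumn": 9, "winter": 12}


def mae(y, y_hat) -> float:
    """Mean absolute error."""
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    if y.shape != y_hat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {y_hat.shape}")
    if y.size == 0:
        raise ValueError("empty input")
    return float(np.mean(np.abs(y - y_hat)))


def quantile_association(y, y_hat, n_bins: int = 10) -> tuple[pd.DataFrame, float]:
    """Empirical quantile pairs at bin midpoints plus Spearman correlation.

    Returns (table with columns q, y_q, yhat_q; rho).  For constant series
    the correlation is undefined and reported as nan.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    y = np.asarray(y, dtype=np.float64)
    y_hat = np.asarray(y_hat, dtype=np.float64)
    q = (np.arange(n_bins) + 0.5) / n_bins
    table = pd.DataFrame({"q": q, "y_q": np.quantile(y, q), "yhat_q": np.quantile(y_hat, q)})
    if np.ptp(y) == 0 or np.ptp(y_hat) == 0:
        rho = float("nan")
    else:
        rho = float(stats.spearmanr(y, y_hat).statistic)
    return table, rho


# ------------------------------------------------------------------------ ICE
@dataclass
class ICEResult:
    """ICE curves for one variable: a grid of values and, per seasonal
    window, the window-averaged predicted productivity at each grid value."""

    variable: str
    grid: np.ndarray
    curves: dict  # season -> (n_grid,) window-averaged curve
    per_day: dict = field(default_factory=dict)  # season -> (n_days, n_grid)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for season, curve in self.curves.items():
            for g, v in zip(self.grid, curve):
                rows.append(
                    {"season": season, "variable": self.variable, "grid_value": g, "mean_P": v}
                )
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def default_grid(df: pd.DataFrame, variable: str, n_grid: int = 25, extend: float = 0.1) -> np.ndarray:
    """25 equally spaced points spanning the variable's observed range,
    extended by 10% on each side (clipped to physical lower bounds)."""
    v = df[variable].to_numpy(dtype=np.float64)
    lo, hi = v.min(), v.max()
    span = hi - lo
    lo, hi = lo - extend * span, hi + extend * span
    if variable in ("phi", "R", "D"):
        lo = max(lo, 0.0)
    if variable == "fappfd":
        lo, hi = max(lo, 0.0), min(hi, 1.0)
    return np.linspace(lo, hi, n_grid)


def seasonal_windows(df: pd.DataFrame, n_days: int = 14) -> dict:
    """Positions (into ``df``) of the first ``n_days`` days of March, June,
    September and December of the evaluation year."""
    dates = pd.to_datetime(df["date"])
    windows = {}
    for season, month in SEASON_WINDOWS.items():
        pos = np.flatnonzero((dates.dt.month == month).to_numpy() & (dates.dt.day <= n_days).to_numpy())
        windows[season] = pos[:n_days]
    return windows


def ice(
    predict_fn,
    df: pd.DataFrame,
    variable: str,
    grid: np.ndarray | None = None,
    windows: dict | None = None,
    n_grid: int = 25,
    mode: str = "per_day",
) -> ICEResult:
    """Individual conditional expectations of one variable.

    ``predict_fn(df) -> (n,)`` maps a full daily table to daily predictions
    (stateful models therefore see a consistent series).  In ``per_day``
    mode the variable is replaced one day at a time and the resulting curves
    are averaged over the window afterwards; ``joint`` replaces the whole
    window at once and averages the window predictions (the two coincide for
    pointwise models and differ only through carried-over state).
    """
    if variable not in df.columns:
        raise ValueError(f"variable {variable!r} not in the model inputs")
    if mode not in ("per_day", "joint"):
        raise ValueError("mode must be 'per_day' or 'joint'")
    grid = grid if grid is not None else default_grid(df, variable, n_grid)
    windows = windows if windows is not None else seasonal_windows(df)

    curves: dict = {}
    per_day: dict = {}
    for season, pos in windows.items():
        pos = np.asarray(pos)
        day_curves = np.empty((len(pos), len(grid)))
        if mode == "joint":
            for j, g in enumerate(grid):
                mod = df.copy()
                mod.loc[mod.index[pos], variable] = g
                pred = np.asarray(predict_fn(mod))
                day_curves[:, j] = pred[pos]
        else:
            for i, p in enumerate(pos):
                for j, g in enumerate(grid):
                    mod = df.copy()
                    mod.loc[mod.index[p], variable] = g
                    day_curves[i, j] = np.asarray(predict_fn(mod))[p]
        curves[season] = day_curves.mean(axis=0)
        per_day[season] = day_curves
    return ICEResult(variable=variable, grid=grid, curves=curves, per_day=per_day)


def ice_departure(a: ICEResult, b: ICEResult) -> float:
    """Normalised departure between two models' ICE curves for the same
    variable: curves are centred (their window mean removed, isolating effect
    shape from level bias) and the mean absolute difference is averaged over
    grid points and seasons."""
    if a.variable != b.variable or len(a.grid) != len(b.grid):
        raise ValueError("ICE results are not comparable")
    total = 0.0
    for season in a.curves:
        ca = a.curves[season] - a.curves[season].mean()
        cb = b.curves[season] - b.curves[season].mean()
        total += float(np.mean(np.abs(ca - cb)))
    return total / len(a.curves)


# --------------------------------------------------------------- experiment IO
@dataclass
class EvalReport:
    """Per-variant accuracy with across-fold spread, quantile association
    and a best-model flag."""

    table: pd.DataFrame  # model, mae, mae_fold_sd, spearman, best
    quantiles: dict  # model -> quantile DataFrame

    def to_json(self, path) -> None:
        doc = {
            "table": self.table.to_dict(orient="records"),
            "quantiles": {m: q.to_dict(orient="list") for m, q in self.quantiles.items()},
        }
        Path(path).write_text(json.dumps(doc, indent=1))


def evaluate_predictions(pred_df: pd.DataFrame) -> EvalReport:
    """Summarise a tidy prediction table with columns (model, fold, y, y_hat).

    Pooled MAE per model, the across-fold spread (sd of per-fold MAEs),
    decile quantile association and Spearman correlation; the lowest pooled
    MAE is flagged best.
    """
    required = {"model", "y", "y_hat"}
    if not required.issubset(pred_df.columns):
        raise ValueError(f"prediction table needs columns {sorted(required)}")
    rows = []
    quantiles = {}
    for model, sub in pred_df.groupby("model", sort=False):
        pooled = mae(sub["y"], sub["y_hat"])
        if "fold" in sub.columns and sub["fold"].nunique() > 1:
            fold_maes = [mae(g["y"], g["y_hat"]) for _, g in sub.groupby("fold")]
            spread = float(np.std(fold_maes))
        else:
            spread = 0.0
        table, rho = quantile_association(sub["y"], sub["y_hat"])
        quantiles[model] = table
        rows.append({"model": model, "mae": pooled, "mae_fold_sd": spread, "spearman": rho})
    table = pd.DataFrame(rows)
    table["best"] = table["mae"] == table["mae"].min()
    return EvalReport(table=table, quantiles=quantiles)


def evaluate_experiment(run_dir) -> EvalReport:
    """Recompute the evaluation report from a run directory's persisted
    per-day prediction CSV (predictions.csv with model, fold, y, y_hat)."""
    path = Path(run_dir) / "predictions.csv"
    if not path.exists():
        raise FileNotFoundError(f"no predictions found under {run_dir}")
    report = evaluate_predictions(pd.read_csv(path))
    report.table.to_csv(Path(run_dir) / "report.csv", index=False)
    report.to_json(Path(run_dir) / "report.json")
    return report
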