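"""Lagged environmental-driver feature table and variable importance.

Annual whale metrics (mean, max, peak date, skew, kurtosis, return
proportion) and environmental indices (PDO anomaly, SST anomaly and
mean, wind, upwelling and spring-transition dates at 48 and 51 degrees
latitude) are assembled into a year-by-(variable x lag) table.  The
relative importance of each lagged variable for an annual response is
scored from univariate penalized-spline fits — one smooth term per
variable, so each score reflects that variable's influence without the
others — as the variable's share of explained deviance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.gam.api import BSplines, GLMGam

__all__ = [
    "ENV_COLUMNS",
    "WHALE_COLUMNS",
    "build_lagged_features",
    "spearman_screen",
    "rank_variable_importance",
    "ImportanceReport",
]

ENV_COLUMNS = [
    "pdo_anomaly",
    "sst_anomaly",
    "sst_mean",
    "wind_speed",
    "upwelling_48",
    "upwelling_51",
    "sti_48",
    "sti_51",
]

WHALE_COLUMNS = [
    "mean_whales",
    "max_whales",
    "peak_date_days",
    "skewness",
    "excess_kurtosis",
    "return_proportion",
]


def build_lagged_features(
    annual: pd.DataFrame,
    fidelity: pd.DataFrame | None = None,
    env: pd.DataFrame | None = None,
    max_lag: int = 4,
    lags: tuple[int, ...] | None = None,
) -> pd.DataFrame:
    """Year-indexed feature table with columns ``<variable>_lag<k>``.

    The lag-k column at year t carries the source value at year t - k,
    so the first k years of each lagged column are missing.  Inputs are
    joined on year; duplicate years are an error.
    """
    frames = [annual]
    if fidelity is not None and not fidelity.empty:
        frames.append(fidelity)
    if env is not None and not env.empty:
        frames.append(env)
    merged = None
    for f in frames:
        if "year" not in f.columns:
            raise ValueError("every input table needs a 'year' column")
        if f["year"].duplicated().any():
            raise ValueError("duplicate years in input table")
        f = f.set_index("year")
        merged = f if merged is None else merged.join(f, how="outer")
    merged = merged.sort_index()
    merged.index = merged.index.astype(int)

    lag_set = lags if lags is not None else tuple(range(0, max_lag + 1))
    variables = [
        c for c in merged.columns
        if c in WHALE_COLUMNS + ENV_COLUMNS or merged[c].dtype.kind in "fi"
    ]
    out = {}
    for var in variables:
        for k in lag_set:
            out[f"{var}_lag{k}"] = merged[var].shift(k)
    table = pd.DataFrame(out, index=merged.index)
    table.index.name = "year"
    return table


def spearman_screen(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Spearman rank-correlation matrix with p-values.

    Returns ``(rs, p)`` symmetric DataFrames with unit diagonal;
    constant columns give NaN entries.
    """
    cols = table.columns
    n = len(cols)
    rs = np.full((n, n), np.nan)
    pv = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i, n):
            sub = table.iloc[:, [i, j]].dropna()
            if i == j:
                rs[i, i] = 1.0
                pv[i, i] = 0.0
                continue
            if len(sub) < 3 or sub.iloc[:, 0].nunique() < 2 or sub.iloc[:, 1].nunique() < 2:
                continue
            r, p = stats.spearmanr(sub.iloc[:, 0], sub.iloc[:, 1])
            rs[i, j] = rs[j, i] = r
            pv[i, j] = pv[j, i] = p
    return (
        pd.DataFrame(rs, index=cols, columns=cols),
        pd.DataFrame(pv, index=cols, columns=cols),
    )


@dataclass
class ImportanceReport:
    """Normalized relative-importance scores for one response."""

    response: str
    scores: pd.Series  # normalized, sums to 1 over included predictors
    deviance_explained: pd.Series  # raw per-variable explained-deviance share
    dropped_collinear: list[str]
    n_rows: int

    @property
    def ranking(self) -> list[str]:
        return list(self.scores.sort_values(ascending=False).index)


def _univariate_deviance_share(
    y: np.ndarray, x: np.ndarray, basis_df: int, alpha_grid: np.ndarray
) -> float:
    """Explained-deviance share of one penalized-spline fit.

    Smoothing is chosen on a fixed alpha grid by generalized
    cross-validation, GCV = n * RSS / (n - edf)^2, which keeps the fit
    deterministic for a given table.
    """
    n = len(y)
    null_dev = float(np.sum((y - y.mean()) ** 2))
    if null_dev == 0:
        return 0.0
    best = None
    for alpha in alpha_grid:
        smoother = BSplines(
            x.reshape(-1, 1), df=[basis_df], degree=[3], include_intercept=False
        )
        model = GLMGam(
            y, exog=np.ones((n, 1)), smoother=smoother, alpha=[float(alpha)]
        )
        try:
            res = model.fit()
        except (np.linalg.LinAlgError, ValueError):
            continue
        edf = float(np.sum(res.get_hat_matrix_diag(observed=True)))
        rss = float(res.deviance)
        denom = max(n - edf, 1e-6)
        gcv = n * rss / denom**2
        if best is None or gcv < best[0]:
            best = (gcv, rss)
    if best is None:
        return 0.0
    return max(0.0, 1.0 - best[1] / null_dev)


def rank_variable_importance(
    table: pd.DataFrame,
    response: str,
    predictors: list[str] | None = None,
    basis_df: int = 5,
    collinearity_cap: float = 0.95,
    alpha_grid: np.ndarray | None = None,
    min_rows: int = 8,
) -> ImportanceReport:
    """Relative variable importance from univariate smooth fits.

    Each predictor is fit alone (intercept + penalized spline) against
    the response; its raw importance is the explained-deviance share of
    that fit, and the normalized scores sum to 1.  Predictors whose
    pairwise |Spearman rs| exceeds ``collinearity_cap`` are screened:
    the later column of each offending pair is dropped.  Deterministic
    given the data and smoothing configuration.
    """
    if response not in table.columns:
        raise ValueError(f"response {response!r} not in table")
    if predictors is None:
        predictors = [c for c in table.columns if c != response]
    if alpha_grid is None:
        alpha_grid = np.logspace(-3, 3, 7)

    usable = []
    for p in predictors:
        sub = table[[response, p]].dropna()
        if len(sub) >= max(min_rows, basis_df + 2) and sub[p].nunique() > basis_df:
            usable.append(p)
        elif len(sub) < max(min_rows, basis_df + 2):
            raise ValueError(
                f"predictor {p!r}: only {len(sub)} complete rows; need "
                f">= {max(min_rows, basis_df + 2)} (reduce basis_df or lags)"
            )
    dropped: list[str] = []
    if len(usable) > 1:
        rs, _ = spearman_screen(table[usable])
        keep: list[str] = []
        for p in usable:
            if any(abs(rs.loc[p, q]) > collinearity_cap for q in keep):
                dropped.append(p)
            else:
                keep.append(p)
        usable = keep

    raw = {}
    for p in usable:
        sub = table[[response, p]].dropna()
        raw[p] = _univariate_deviance_share(
            sub[response].to_numpy(float), sub[p].to_numpy(float),
            basis_df, alpha_grid,
        )
    raw_s = pd.Series(raw, dtype=float)
    total = raw_s.sum()
    scores = raw_s / total if total > 0 else pd.Series(
        np.full(len(raw_s), 1.0 / len(raw_s)), index=raw_s.index
    )
    return ImportanceReport(
        response=response,
        scores=scores,
        deviance_explained=raw_s,
        dropped_collinear=dropped,
        n_rows=int(table[[response] + usable].dropna().shape[0]) if usable else 0,
    )
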