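"""Time-series diagnostics for transect count series.

Wraps the standard battery used on within- and between-year whale-count
series: autocorrelation and partial autocorrelation with 95% bands,
persistence (naive) forecast residuals, the Dickey-Fuller stationarity
test, the non-parametric runs test, the Ljung-Box portmanteau statistic,
and lagged cross-correlation between annual series.

The ACF uses the biased (1/n) estimator with +/-1.96/sqrt(n) bands; the
PACF uses the Durbin-Levinson recursion on the biased ACF, so
pacf[1] == acf[1] by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.sandbox.stats.runs import runstest_1samp
from statsmodels.stats.diagnostic import acorr_ljungbox
from statsmodels.tsa.stattools import acf as _sm_acf
from statsmodels.tsa.stattools import adfuller
from statsmodels.tsa.stattools import pacf as _sm_pacf

__all__ = [
    "acf",
    "pacf",
    "persistence_residuals",
    "PersistenceResult",
    "stationarity_test",
    "StationarityResult",
    "runs_test",
    "ljung_box",
    "cross_correlation",
    "diagnose_series",
]


def _validate(series, max_lag: int | None = None) -> np.ndarray:
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    if max_lag is not None and len(x) <= max_lag:
        raise ValueError(f"series length {len(x)} must exceed max_lag {max_lag}")
    if np.ptp(x) == 0:
        raise ValueError("constant series: autocorrelation undefined")
    return x


def acf(series, max_lag: int) -> tuple[np.ndarray, float]:
    """Autocorrelation at lags 0..max_lag with the 95% band half-width.

    Returns ``(coefficients, band)`` where the white-noise band is
    +/-1.96/sqrt(n).  acf[0] is always 1.
    """
    x = _validate(series, max_lag)
    coeffs = _sm_acf(x, nlags=max_lag, adjusted=False, fft=False)
    return coeffs, 1.96 / np.sqrt(len(x))


def pacf(series, max_lag: int) -> tuple[np.ndarray, float]:
    """Partial autocorrelation at lags 0..max_lag (Durbin-Levinson).

    Lags are limited to below half the sample size, where the recursion
    is well determined.
    """
    x = _validate(series, max_lag)
    if max_lag >= len(x) // 2:
        raise ValueError(
            f"max_lag {max_lag} must be below half the series length {len(x)}"
        )
    coeffs = _sm_pacf(x, nlags=max_lag, method="ldb")
    return coeffs, 1.96 / np.sqrt(len(x))


@dataclass
class PersistenceResult:
    """Residuals of the naive (persistence) forecast obs[t-1] -> obs[t]."""

    residuals: np.ndarray
    summary: dict
    test_summary: dict
    train_size: int

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.summary])


def _describe(res: np.ndarray) -> dict:
    if len(res) == 0:
        return {"count": 0, "mean": np.nan, "sd": np.nan, "min": np.nan, "max": np.nan}
    return {
        "count": int(len(res)),
        "mean": float(res.mean()),
        "sd": float(res.std(ddof=1)) if len(res) > 1 else 0.0,
        "min": float(res.min()),
        "max": float(res.max()),
    }


def persistence_residuals(series, train_fraction: float = 0.66) -> PersistenceResult:
    """Residual errors of the persistence forecast.

    residual[t] = obs[t] - obs[t-1] for every consecutive pair, so the
    residual count is len(series) - 1.  The chronological first
    ``train_fraction`` of the series is the training window; the summary
    over the held-out residuals is reported alongside the full summary.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 3:
        raise ValueError("persistence residuals need at least 3 observations")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    res = np.diff(x)
    train_size = int(round(train_fraction * len(x)))
    test_res = res[max(train_size - 1, 0):]
    return PersistenceResult(
        residuals=res,
        summary=_describe(res),
        test_summary=_describe(test_res),
        train_size=train_size,
    )


@dataclass
class StationarityResult:
    statistic: float
    p_value: float
    critical_values: dict = field(default_factory=dict)
    lag_order: int = 0

    def rejects_unit_root(self, level: str = "5%") -> bool:
        return self.statistic < self.critical_values[level]


def stationarity_test(series, lag_order: int = 0, regression: str = "c") -> StationarityResult:
    """Dickey-Fuller test for a unit root.

    Defaults to the non-augmented form (lag order 0) with an intercept.
    Rejection of the null (statistic below the critical value) indicates
    a stationary series with no repetitive temporal trend.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 10:
        raise ValueError("stationarity test needs at least 10 observations")
    stat, pval, _, _, crit = adfuller(
        x, maxlag=lag_order, regression=regression, autolag=None
    )
    return StationarityResult(
        statistic=float(stat),
        p_value=float(pval),
        critical_values={k: float(v) for k, v in crit.items()},
        lag_order=lag_order,
    )


def runs_test(series) -> tuple[float, float]:
    """Two-sided runs test for randomness, dichotomized about the median.

    Returns ``(z, p_value)`` from the normal approximation.  A small p
    indicates either too few runs (persistence) or too many
    (alternation).
    """
    x = np.asarray(series, dtype=float)
    med = np.median(x)
    above = int(np.sum(x >= med))
    below = int(np.sum(x < med))
    if above < 2 or below < 2:
        raise ValueError("degenerate dichotomy: need >=2 observations on each side of the median")
    z, p = runstest_1samp(x, cutoff="median", correction=False)
    return float(z), float(p)


def ljung_box(series, lags: int) -> pd.DataFrame:
    """Ljung-Box portmanteau statistic at lags 1..lags.

    The statistic is nonnegative and nondecreasing in the included lag.
    """
    x = _validate(series, lags)
    out = acorr_ljungbox(x, lags=list(range(1, lags + 1)), return_df=True)
    return out.rename(columns={"lb_stat": "statistic", "lb_pvalue": "p_value"})


def cross_correlation(a, b, max_lag: int = 10) -> pd.DataFrame:
    """Lagged cross-correlation between two year-aligned series.

    At lag k the reported value is corr(a[t], b[t-k]) — positive lags
    mean b leads a.  Missing years are handled by pairwise deletion;
    lags with fewer than 3 overlapping pairs are NaN and flagged.
    """
    if max_lag > 10:
        raise ValueError("lags above 10 years are not supported")
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    if len(xa) != len(xb):
        raise ValueError("series must be aligned to the same years")
    rows = []
    for k in range(0, max_lag + 1):
        aa = xa[k:]
        bb = xb[: len(xb) - k] if k else xb
        mask = np.isfinite(aa) & np.isfinite(bb)
        n = int(mask.sum())
        if n < 3 or np.ptp(aa[mask]) == 0 or np.ptp(bb[mask]) == 0:
            rows.append({"lag": k, "r": np.nan, "n": n, "flag": "insufficient"})
            continue
        r = float(np.corrcoef(aa[mask], bb[mask])[0, 1])
        rows.append({"lag": k, "r": r, "n": n, "flag": ""})
    return pd.DataFrame(rows, columns=["lag", "r", "n", "flag"])


def diagnose_series(series, max_lag: int = 10, train_fraction: float = 0.66) -> dict:
    """Run the full diagnostic battery on one series; returns a JSON-able dict."""
    x = np.asarray(series, dtype=float)
    max_lag = max(min(max_lag, len(x) // 2 - 1), 1)
    acf_c, band = acf(x, max_lag)
    pacf_c, _ = pacf(x, max_lag)
    pers = persistence_residuals(x, train_fraction)
    out = {
        "n": int(len(x)),
        "acf": acf_c.tolist(),
        "pacf": pacf_c.tolist(),
        "conf_band": float(band),
        "residual_summary": pers.summary,
        "residual_test_summary": pers.test_summary,
    }
    if len(x) >= 10:
        st = stationarity_test(x)
        out["stationarity"] = {
            "statistic": st.statistic,
            "p_value": st.p_value,
            "critical_values": st.critical_values,
        }
        lb = ljung_box(x, min(max_lag, len(x) // 2))
        out["ljung_box"] = {
            "lags": lb.index.tolist(),
            "statistic": lb["statistic"].tolist(),
            "p_value": lb["p_value"].tolist(),
        }
    try:
        z, p = runs_test(x)
        out["runs"] = {"z": z, "p_value": p}
    except ValueError:
        out["runs"] = None
    return out
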