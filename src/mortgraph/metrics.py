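"""Forecast evaluation: error metrics, age summaries, prediction intervals.

All metrics are computed on natural-log mortality. MAPE is reported in
percent; entries whose true value is exactly zero are excluded from the
MAPE average and their count is reported (log rates are essentially never
zero, but the contract is explicit).

Prediction intervals follow the RMSFE recipe: the root mean squared forecast
error per (country, age) is estimated on a rolling-origin calibration
hold-out inside the training years, and the interval at level q is the
point forecast +/- z_{(1+q)/2} * RMSFE with the Gaussian quantile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "MetricReport", "IntervalResult", "metrics_all", "metrics_country",
    "percent_improvement", "age_rmse_summary", "age_error_profile",
    "prediction_intervals", "residual_trend_slope",
]


@dataclass
class MetricReport:
    """Global + per-year error summary for one model's forecast."""

    rmse_all: float
    mae_all: float
    mape_all: float
    rmse_by_year: np.ndarray
    mape_excluded: int = 0

    def as_dict(self) -> dict:
        return {
            "rmse_all": self.rmse_all, "mae_all": self.mae_all,
            "mape_all": self.mape_all,
            "rmse_by_year": [float(v) for v in self.rmse_by_year],
            "mape_excluded": self.mape_excluded,
        }

    def to_csv(self, path) -> None:
        import pandas as pd

        rows = [{"metric": "rmse_all", "value": self.rmse_all},
                {"metric": "mae_all", "value": self.mae_all},
                {"metric": "mape_all_pct", "value": self.mape_all}]
        rows += [{"metric": f"rmse_year_{i + 1}", "value": float(v)}
                 for i, v in enumerate(self.rmse_by_year)]
        pd.DataFrame(rows).to_csv(path, index=False)


def _check_shapes(pred: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    return pred, truth


def metrics_all(pred: np.ndarray, truth: np.ndarray) -> MetricReport:
    """RMSE/MAE/MAPE over an (m, T, d) block plus RMSE per forecast year."""
    pred, truth = _check_shapes(pred, truth)
    if pred.ndim != 3:
        raise ValueError("expected (m, T, d) arrays")
    err = truth - pred
    rmse = float(np.sqrt((err ** 2).mean()))
    mae = float(np.abs(err).mean())
    nz = truth != 0
    excluded = int((~nz).sum())
    mape = float(100.0 * np.abs(err[nz] / truth[nz]).mean())
    rmse_t = np.sqrt((err ** 2).mean(axis=(0, 2)))
    return MetricReport(rmse, mae, mape, rmse_t, excluded)


def metrics_country(pred: np.ndarray, truth: np.ndarray) -> dict:
    """RMSE/MAE/MAPE for one country's (T, d) forecast block."""
    pred, truth = _check_shapes(pred, truth)
    if pred.ndim != 2:
        raise ValueError("expected (T, d) arrays")
    rep = metrics_all(pred[None], truth[None])
    return {"rmse": rep.rmse_all, "mae": rep.mae_all, "mape": rep.mape_all,
            "mape_excluded": rep.mape_excluded}


def percent_improvement(rmse_model1: np.ndarray, rmse_model2: np.ndarray) -> float:
    """Percent improvement of model 2 over model 1 on country-mean RMSE:
    (mean1 - mean2) / mean1 * 100."""
    r1 = np.asarray(rmse_model1, dtype=float)
    r2 = np.asarray(rmse_model2, dtype=float)
    if r1.shape != r2.shape:
        raise ValueError("lists must have equal length")
    mean1, mean2 = r1.mean(), r2.mean()
    if mean1 <= 0:
        raise ValueError("model-1 mean RMSE must be positive")
    return float((mean1 - mean2) / mean1 * 100.0)


def age_rmse_summary(pred: np.ndarray, truth: np.ndarray) -> dict:
    """Per-age RMSE over forecast years plus its mean and quartiles.

    Quartiles use linear interpolation between order statistics.
    """
    pred, truth = _check_shapes(pred, truth)
    if pred.ndim == 2:
        pred, truth = pred[None], truth[None]
    err = truth - pred
    per_age = np.sqrt((err ** 2).mean(axis=(0, 1)))
    q1, q3 = np.percentile(per_age, [25, 75], method="linear")
    return {"per_age_rmse": per_age, "mean": float(per_age.mean()),
            "q1": float(q1), "q3": float(q3)}


def age_error_profile(pred: np.ndarray, truth: np.ndarray) -> dict:
    """Signed per-age error profile.

    ``profile`` implements, per age group, mean(truth) - mean(pred) minus
    the estimated standard deviation of the residuals in that age group
    (note this is negative when pred == truth and residual sd dominates);
    ``mean_residual`` is the plain signed mean residual, reported alongside.
    """
    pred, truth = _check_shapes(pred, truth)
    if pred.ndim == 2:
        pred, truth = pred[None], truth[None]
    resid = truth - pred                       # (m, T, d)
    mean_resid = resid.mean(axis=(0, 1))
    sd = resid.std(axis=(0, 1), ddof=1) if resid.shape[0] * resid.shape[1] > 1 \
        else np.zeros(resid.shape[2])
    return {"profile": mean_resid - sd, "mean_residual": mean_resid}


def residual_trend_slope(pred: np.ndarray, truth: np.ndarray) -> float:
    """Least-squares slope of the pooled residuals against forecast year."""
    pred, truth = _check_shapes(pred, truth)
    if pred.ndim == 2:
        pred, truth = pred[None], truth[None]
    resid = (truth - pred).mean(axis=(0, 2))   # (T,)
    t = np.arange(len(resid), dtype=float)
    slope, _ = np.polyfit(t, resid, 1)
    return float(slope)


@dataclass
class IntervalResult:
    """Gaussian prediction intervals scaled by per-(country, age) RMSFE."""

    lower: np.ndarray        # (m, T, d)
    upper: np.ndarray
    point: np.ndarray
    level: float
    rmsfe: np.ndarray        # (m, d)
    z: float

    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def to_csv(self, path, countries=None, years=None, ages=None) -> None:
        """Long-format CSV: one row per (country, year, age) with bounds."""
        import pandas as pd

        m, T, d = self.point.shape
        countries = countries or [f"c{i}" for i in range(m)]
        years = np.arange(T) if years is None else np.asarray(years)
        ages = np.arange(d) if ages is None else np.asarray(ages)
        frames = []
        for i, code in enumerate(countries):
            for j, year in enumerate(years):
                frames.append(pd.DataFrame({
                    "country": code, "year": int(year), "age": ages,
                    "point": self.point[i, j], "lower": self.lower[i, j],
                    "upper": self.upper[i, j],
                }))
        pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def prediction_intervals(point: np.ndarray, calibration_residuals: np.ndarray,
                         level: float = 0.95) -> IntervalResult:
    """Build intervals point +/- z * RMSFE.

    ``point`` has shape (m, T, d); ``calibration_residuals`` has shape
    (m, n_calib, d) and comes from a hold-out inside the training years
    (forecast minus observed on the calibration window).
    """
    point = np.asarray(point, dtype=float)
    resid = np.asarray(calibration_residuals, dtype=float)
    if resid.ndim != 3 or resid.shape[1] == 0:
        raise ValueError("calibration residual set is empty")
    if resid.shape[0] != point.shape[0] or resid.shape[2] != point.shape[2]:
        raise ValueError("calibration residuals do not match the point forecast")
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    rmsfe = np.sqrt((resid ** 2).mean(axis=1))        # (m, d)
    z = float(stats.norm.ppf((1.0 + level) / 2.0))
    half = z * rmsfe[:, None, :]
    return IntervalResult(point - half, point + half, point, level, rmsfe, z)
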