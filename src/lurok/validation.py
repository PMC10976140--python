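"""Leave-one-site-out cross-validation and accuracy metrics.

Model skill is summarized with RMSE and two R² flavors:

* ``r2_mse`` = max(0, 1 − RMSE² / (Σ(yᵢ−ȳ)²/n)) — fit to the 1:1 line,
  the primary performance measure;
* ``r2_reg`` = squared Pearson correlation between observations and
  predictions — fit to the regression line, typically higher, reported for
  comparability with other studies.

LOOCV holds out one monitoring site at a time and refits the *entire* model
on the remaining sites — the LUR (including any internal standardization)
and, when kriging is enabled, the empirical variogram, its parametric fit,
and the residual support. The held-out site never contributes to its own
prediction in any way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from lurok.kriging import fit_hybrid, hybrid_predict

logger = logging.getLogger(__name__)


def rmse(y, y_hat) -> float:
    """Root-mean-square error sqrt(mean((y − ŷ)²)), in µg/m³."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.size == 0 or y.shape != y_hat.shape:
        raise ValueError("y and y_hat must be nonempty and equal-length")
    return float(np.sqrt(np.mean((y - y_hat) ** 2)))


def r2_mse(y, y_hat) -> float:
    """MSE-based R², clamped at 0: max(0, 1 − RMSE²/(Σ(yᵢ−ȳ)²/n))."""
    y = np.asarray(y, dtype=float)
    var = float(np.mean((y - y.mean()) ** 2))
    if var == 0:
        raise ValueError("constant observations: r2_mse undefined")
    return max(0.0, 1.0 - rmse(y, y_hat) ** 2 / var)


def r2_reg(y, y_hat) -> float:
    """Regression-based R²: squared Pearson correlation of y and ŷ.
    Zero-variance predictions give 0 (with a warning)."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if np.var(y) == 0:
        raise ValueError("constant observations: r2_reg undefined")
    if np.var(y_hat) == 0:
        logger.warning("zero-variance predictions: r2_reg reported as 0")
        return 0.0
    r = np.corrcoef(y, y_hat)[0, 1]
    return float(r**2)


@dataclass
class CVResult:
    """Pooled held-out predictions and summary metrics from LOOCV."""

    predictions: pd.DataFrame  # site_id, observed, predicted
    failed_folds: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.predictions)

    @property
    def rmse(self) -> float:
        return rmse(self.predictions["observed"], self.predictions["predicted"])

    @property
    def r2_mse(self) -> float:
        return r2_mse(self.predictions["observed"], self.predictions["predicted"])

    @property
    def r2_reg(self) -> float:
        return r2_reg(self.predictions["observed"], self.predictions["predicted"])

    def summary(self) -> dict:
        return {
            "n": self.n,
            "rmse": self.rmse,
            "r2_mse": self.r2_mse,
            "r2_reg": self.r2_reg,
            "n_failed_folds": len(self.failed_folds),
        }


def loocv(
    family: str,
    X: pd.DataFrame,
    y,
    coords: np.ndarray,
    lur_spec=None,
    expected_sign=None,
    kriging: bool = False,
    variogram_family: str = "exponential",
    return_lur_only: bool = False,
) -> CVResult | tuple[CVResult, CVResult]:
    """Leave-one-site-out cross-validation of a LUR or LUR-OK model.

    Sites with missing observations are dropped beforehand. Each fold refits
    the full model on the remaining sites and predicts the held-out site.
    With ``kriging`` and ``return_lur_only``, the bare-LUR held-out
    predictions recorded along the way are returned as a second CVResult
    (the LUR fits are identical, so this costs nothing extra). Folds whose
    fit fails are excluded from the metrics with a warning.
    """
    y = pd.Series(np.asarray(y, dtype=float), index=X.index)
    coords = np.asarray(coords, dtype=float)
    avail = y.notna().to_numpy()
    X, y, coords = X.loc[avail], y.loc[avail], coords[avail]
    if len(y) < 5:
        raise ValueError("need at least 5 sites with available observations")

    rows, lur_rows, failed = [], [], []
    for i, site in enumerate(X.index):
        mask = np.ones(len(y), dtype=bool)
        mask[i] = False
        try:
            model = fit_hybrid(
                family,
                X.iloc[mask],
                y.iloc[mask].to_numpy(),
                coords[mask],
                lur_spec=lur_spec,
                expected_sign=expected_sign,
                kriging=kriging,
                variogram_family=variogram_family,
            )
            pred = hybrid_predict(model, X.iloc[[i]], coords[[i]])[0]
            if kriging and return_lur_only:
                lur_pred = max(float(model.lur.predict(X.iloc[[i]])[0]), 0.0)
                lur_rows.append((site, float(y.iloc[i]), lur_pred))
        except Exception as exc:
            logger.warning("fold for site %s failed: %s", site, exc)
            failed.append(str(site))
            continue
        rows.append((site, float(y.iloc[i]), float(pred)))

    preds = pd.DataFrame(rows, columns=["site_id", "observed", "predicted"])
    result = CVResult(preds, failed)
    if kriging and return_lur_only:
        lur_result = CVResult(
            pd.DataFrame(lur_rows, columns=["site_id", "observed", "predicted"]),
            list(failed),
        )
        return result, lur_result
    return result
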