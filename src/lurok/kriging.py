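"""Semivariograms, ordinary kriging, and the hybrid LUR-OK predictor.

LUR residuals at monitoring sites are usually spatially correlated, so the
hybrid model explains them with ordinary kriging (OK) in a second step: fit
the LUR, compute training residuals, estimate an empirical semivariogram
(Matheron estimator), fit a parametric variogram model by weighted least
squares, and krige the residuals to prediction locations. The hybrid
prediction is LUR prediction + kriged residual.

The OK system at a target s0 with support points s1..sn solves

    [ Γ  1 ] [ w ]   [ γ(s0) ]
    [ 1ᵀ 0 ] [ μ ] = [   1   ]

where Γ_ij = γ(|si−sj|), giving weights that sum to 1 (unbiasedness) and a
kriging variance wᵀγ(s0) + μ. With a zero nugget OK interpolates exactly.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.spatial.distance import cdist, pdist, squareform

from lurok.models import LURModel, fit_lur

logger = logging.getLogger(__name__)


@dataclass
class VariogramModel:
    """Parametric semivariogram γ(h) = nugget + partial_sill · g(h/range)."""

    family: str = "exponential"  # exponential | spherical | gaussian
    nugget: float = 0.0  # (µg/m³)²
    partial_sill: float = 1.0  # (µg/m³)²
    range_: float = 1.0  # meters

    def __post_init__(self):
        if self.family not in ("exponential", "spherical", "gaussian"):
            raise ValueError(f"unknown variogram family {self.family!r}")
        if self.nugget < 0 or self.partial_sill < 0:
            raise ValueError("nugget and partial_sill must be nonnegative")
        if self.range_ <= 0:
            raise ValueError("range must be positive")

    def __call__(self, h: np.ndarray) -> np.ndarray:
        h = np.asarray(h, dtype=float)
        r = self.range_
        if self.family == "exponential":
            g = 1.0 - np.exp(-h / r)
        elif self.family == "gaussian":
            g = 1.0 - np.exp(-((h / r) ** 2))
        else:  # spherical
            u = np.minimum(h / r, 1.0)
            g = 1.5 * u - 0.5 * u**3
        out = self.nugget + self.partial_sill * g
        return np.where(h == 0, 0.0, out)  # γ(0) = 0 by definition


def empirical_variogram(
    residuals: np.ndarray,
    coords: np.ndarray,
    n_bins: int = 12,
    max_lag: float | None = None,
) -> pd.DataFrame:
    """Matheron empirical semivariogram γ̂(h) = Σ (z_i − z_j)² / (2 N(h)).

    Pairs are binned by Euclidean separation into ``n_bins`` equal-width
    bins up to ``max_lag`` (default: half the maximum inter-site distance).
    Returns a frame with columns ``lag`` (mean pair distance per bin),
    ``gamma`` and ``n_pairs``; empty bins are dropped.
    """
    z = np.asarray(residuals, dtype=float)
    coords = np.asarray(coords, dtype=float)
    if len(z) < 10:
        raise ValueError("need at least 10 sites for a variogram")
    d = pdist(coords)
    if max_lag is None:
        max_lag = d.max() / 2.0
    if max_lag <= 0:
        raise ValueError("max_lag must be positive")
    sq = pdist(z[:, None], metric="sqeuclidean")
    edges = np.linspace(0.0, max_lag, n_bins + 1)
    which = np.digitize(d, edges[1:-1])
    inside = d <= max_lag
    rows = []
    for b in range(n_bins):
        m = inside & (which == b)
        n = int(m.sum())
        if n == 0:
            continue
        rows.append((float(d[m].mean()), float(sq[m].sum() / (2 * n)), n))
    emp = pd.DataFrame(rows, columns=["lag", "gamma", "n_pairs"])
    if np.allclose(z, z[0]):
        logger.warning("all residuals identical: flat zero variogram")
    return emp


def fit_variogram(
    emp: pd.DataFrame, family: str = "exponential"
) -> VariogramModel:
    """Fit a parametric variogram to empirical points by weighted least
    squares with weights N(h)/h², box-constrained nonnegative, multistarted
    from method-of-moments initial values. A flat empirical variogram
    returns a pure-nugget model with a warning."""
    if len(emp) < 3:
        raise ValueError("need at least 3 non-empty bins")
    h = emp["lag"].to_numpy(dtype=float)
    g = emp["gamma"].to_numpy(dtype=float)
    w = np.sqrt(emp["n_pairs"].to_numpy(dtype=float)) / h  # sqrt of N/h²

    sill0 = max(g[-max(1, len(g) // 3):].mean(), 1e-12)
    if g.std() <= 1e-12 * max(g.mean(), 1.0):
        warnings.warn("flat empirical variogram: returning pure-nugget model")
        return VariogramModel(family, nugget=float(g.mean()), partial_sill=1e-12 * max(sill0, 1.0), range_=h.max())

    def resid(theta):
        nug, psill, rng_ = theta
        vm = VariogramModel(family, max(nug, 0.0), max(psill, 1e-15), max(rng_, 1e-9))
        return w * (vm(h) - g)

    starts = [
        (max(g[0] / 2, 0.0), sill0, h.max() / 3),
        (0.0, sill0, h.max()),
        (g[0], max(sill0 - g[0], sill0 / 2), h.max() / 10),
    ]
    best = None
    hi_range = 100 * h.max()
    for s0 in starts:
        try:
            res = least_squares(
                resid,
                x0=np.asarray(s0, dtype=float).clip([0, 1e-12, 1e-6], None),
                bounds=([0.0, 1e-12, 1e-6], [np.inf, np.inf, hi_range]),
                xtol=1e-12,
                ftol=1e-12,
            )
        except Exception:  # pragma: no cover - defensive
            continue
        if best is None or res.cost < best.cost:
            best = res
    nug, psill, rng_ = best.x
    return VariogramModel(family, float(nug), float(psill), float(rng_))


# ---------------------------------------------------------------------------
# ordinary kriging


def ok_predict(
    support_coords: np.ndarray,
    support_values: np.ndarray,
    variogram: VariogramModel,
    target_coords: np.ndarray,
    return_weights: bool = False,
):
    """Ordinary kriging of ``support_values`` to ``target_coords``.

    Returns ``(predictions, variances)`` (and the weight matrix + Lagrange
    multipliers when ``return_weights``). Weights sum to 1 for every target;
    with a zero nugget a target coinciding with a support point reproduces
    that support value exactly.
    """
    s = np.asarray(support_coords, dtype=float)
    z = np.asarray(support_values, dtype=float)
    t = np.atleast_2d(np.asarray(target_coords, dtype=float))
    n = len(s)
    if n < 2:
        raise ValueError("need at least 2 support points")
    dmat = squareform(pdist(s))
    off = dmat[np.triu_indices(n, 1)]
    if variogram.nugget == 0 and np.any(off == 0):
        iu = np.triu_indices(n, 1)
        k = int(np.argmin(off))
        i, j = int(iu[0][k]), int(iu[1][k])
        raise ValueError(
            f"duplicate support coordinates at rows {i} and {j} with zero "
            "nugget: singular kriging system"
        )
    A = np.empty((n + 1, n + 1))
    A[:n, :n] = variogram(dmat)
    A[:n, n] = 1.0
    A[n, :n] = 1.0
    A[n, n] = 0.0
    # nugget acts between distinct points but not at a point with itself;
    # γ(0)=0 on the diagonal keeps exact interpolation when nugget=0
    B = np.empty((n + 1, t.shape[0]))
    B[:n] = variogram(cdist(s, t))
    B[n] = 1.0
    sol = np.linalg.solve(A, B)
    w = sol[:n]  # (n, m)
    mu = sol[n]
    pred = w.T @ z
    var = np.einsum("nm,nm->m", w, B[:n]) + mu
    var = np.maximum(var, 0.0)
    if return_weights:
        return pred, var, w.T, mu
    return pred, var


# ---------------------------------------------------------------------------
# hybrid LUR-OK


@dataclass
class HybridModel:
    """A fitted LUR model plus the kriging machinery over its residuals."""

    lur: LURModel
    variogram: VariogramModel | None
    support_coords: np.ndarray | None
    support_residuals: np.ndarray | None
    empirical: pd.DataFrame | None = None

    @property
    def kriging_enabled(self) -> bool:
        return self.variogram is not None


def fit_hybrid(
    family: str,
    X,
    y,
    coords: np.ndarray,
    lur_spec=None,
    expected_sign=None,
    kriging: bool = True,
    variogram_family: str = "exponential",
    n_bins: int = 12,
) -> HybridModel:
    """Fit a LUR model and, when ``kriging``, a variogram on its residuals.

    The residual support is exactly the training sites. With kriging off the
    hybrid is the plain LUR model under the same interface.
    """
    coords = np.asarray(coords, dtype=float)
    yarr = np.asarray(y, dtype=float)
    if len(coords) != len(yarr):
        raise ValueError("coords must align with X rows")
    lur = fit_lur(family, X, yarr, lur_spec, expected_sign=expected_sign)
    if not kriging:
        return HybridModel(lur, None, None, None)
    resid = yarr - lur.predict(X)
    emp = empirical_variogram(resid, coords, n_bins=n_bins)
    if len(emp) >= 3:
        vm = fit_variogram(emp, family=variogram_family)
    else:  # too few sites/bins: fall back to pure nugget (OK -> mean)
        vm = VariogramModel(variogram_family, nugget=float(resid.var()) or 1e-12,
                            partial_sill=1e-12, range_=1.0)
    return HybridModel(lur, vm, coords, resid, emp)


def hybrid_predict(
    model: HybridModel,
    X_new,
    coords_new: np.ndarray | None = None,
    floor_at_zero: bool = True,
) -> np.ndarray:
    """Hybrid prediction: LUR prediction plus the kriged residual.

    Negative concentrations are floored at 0 (logged count) unless
    ``floor_at_zero`` is disabled.
    """
    pred = model.lur.predict(X_new)
    if model.kriging_enabled:
        if coords_new is None:
            raise ValueError("coords_new required when kriging is enabled")
        kr, _ = ok_predict(
            model.support_coords,
            model.support_residuals,
            model.variogram,
            np.asarray(coords_new, dtype=float),
        )
        pred = pred + kr
    if floor_at_zero:
        neg = int((pred < 0).sum())
        if neg:
            logger.info("flooring %d negative prediction(s) at 0", neg)
        pred = np.maximum(pred, 0.0)
    return pred
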