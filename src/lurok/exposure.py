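"""Gridded exposure surfaces and population-weighted comparison of models.

Fitted hybrid models predict concentrations at 1-km grid-cell centers; each
person is assigned the exposure of their cell. The population-weighted
exposure estimate (PEE) is Σ popᵢ·predᵢ / Σ popᵢ. For model comparison,
cells are classified into person-level exposure quartiles (cutpoints are
the 25/50/75% quantiles of the exposure distribution *over persons*, not
over cells) and the population share that two models place in different
quartiles is tabulated in a 4×4 misclassification matrix. Per-cell
coefficient of variation and pairwise Pearson correlations quantify
cross-model divergence of the raw surfaces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from lurok.kriging import HybridModel, hybrid_predict

logger = logging.getLogger(__name__)


def predict_surface(
    model: HybridModel, grid: pd.DataFrame, covariate_columns: list[str] | None = None
) -> pd.DataFrame:
    """Hybrid prediction at every grid-cell center.

    ``grid`` needs grid_id, x, y and the model's training covariate columns
    (a missing one raises, naming it). Returns grid_id + prediction, with
    negatives floored at 0 (count logged)."""
    cols = covariate_columns or model.lur.columns
    missing = [c for c in cols if c not in grid.columns]
    if missing:
        raise ValueError(f"grid is missing covariate column(s): {missing}")
    X = grid.set_index("grid_id")[cols]
    pred = hybrid_predict(model, X, grid[["x", "y"]].to_numpy())
    return pd.DataFrame({"grid_id": grid["grid_id"], "prediction": pred})


def population_weighted_mean(surface: pd.DataFrame, grid: pd.DataFrame) -> float:
    """PEE over the grid: Σ popᵢ·predᵢ / Σ popᵢ (µg/m³)."""
    m = surface.merge(grid[["grid_id", "population"]], on="grid_id", validate="1:1")
    total = m["population"].sum()
    if total <= 0:
        raise ValueError("total population is zero")
    return float((m["population"] * m["prediction"]).sum() / total)


def _weighted_quartile_cutpoints(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Person-level quantile cutpoints: smallest exposure x whose cumulative
    population share reaches q, for q in {0.25, 0.5, 0.75}."""
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cum = np.cumsum(w) / w.sum()
    cuts = []
    for q in (0.25, 0.50, 0.75):
        idx = int(np.searchsorted(cum, q - 1e-12))
        cuts.append(v[min(idx, len(v) - 1)])
    return np.asarray(cuts)


@dataclass
class QuartileClassification:
    classes: pd.Series  # grid_id -> {1,2,3,4}
    cutpoints: np.ndarray  # 3 exposure values, µg/m³
    weighting: str  # population | grid


def quartile_classify(
    surface: pd.DataFrame, grid: pd.DataFrame, weighting: str = "population"
) -> QuartileClassification:
    """Classify grid cells into exposure quartiles.

    Under ``population`` weighting the cutpoints are quantiles of exposure
    over persons (each person carries their cell's exposure) — exactly the
    empirical quartiles of the per-person expansion. ``grid`` weighting
    treats every cell equally. Ties at a cutpoint go to the lower quartile:
    class = 1 + #{cutpoints strictly below the cell's exposure}.
    """
    if len(surface) < 4:
        raise ValueError("need at least 4 cells")
    m = surface.merge(grid[["grid_id", "population"]], on="grid_id", validate="1:1")
    vals = m["prediction"].to_numpy(dtype=float)
    if weighting == "population":
        w = m["population"].to_numpy(dtype=float)
    elif weighting == "grid":
        w = np.ones(len(m))
    else:
        raise ValueError("weighting must be 'population' or 'grid'")
    if np.ptp(vals) == 0:
        logger.warning("all predictions identical: every cell in quartile 1")
        cuts = np.repeat(vals[0], 3)
    else:
        cuts = _weighted_quartile_cutpoints(vals, w)
    classes = 1 + (vals[:, None] > cuts[None, :]).sum(axis=1)
    return QuartileClassification(
        pd.Series(classes, index=m["grid_id"], name="quartile"),
        cuts,
        weighting,
    )


@dataclass
class MisclassificationReport:
    """Population-share 4×4 cross-tab of quartile assignments by two models.

    ``matrix[a-1, b-1]`` is the % of population in quartile a under model A
    and quartile b under model B. ``total`` is the off-diagonal share;
    overestimated (B above A) + underestimated (B below A) = total;
    ``non_adjacent`` counts shares misclassified by 2+ quartiles.
    """

    matrix: np.ndarray  # 4x4, percentages summing to 100
    total: float
    overestimated: float
    underestimated: float
    non_adjacent: float

    @property
    def diagonal(self) -> np.ndarray:
        return np.diag(self.matrix)

    def to_dict(self) -> dict:
        return {
            "matrix_percent": self.matrix.tolist(),
            "total_misclassified_percent": self.total,
            "overestimated_percent": self.overestimated,
            "underestimated_percent": self.underestimated,
            "non_adjacent_percent": self.non_adjacent,
        }


def misclassification(
    class_a: QuartileClassification,
    class_b: QuartileClassification,
    grid: pd.DataFrame,
) -> MisclassificationReport:
    """Population-weighted quartile misclassification between two models."""
    if not class_a.classes.index.equals(class_b.classes.index):
        raise ValueError("classifications cover different grids")
    pop = (
        grid.set_index("grid_id")["population"]
        .reindex(class_a.classes.index)
        .to_numpy(dtype=float)
    )
    if np.isnan(pop).any():
        raise ValueError("grid does not cover all classified cells")
    M = np.zeros((4, 4))
    a = class_a.classes.to_numpy() - 1
    b = class_b.classes.to_numpy() - 1
    np.add.at(M, (a, b), pop)
    M = 100.0 * M / pop.sum()
    upper = np.triu(M, 1).sum()
    lower = np.tril(M, -1).sum()
    far = sum(
        M[i, j] for i in range(4) for j in range(4) if abs(i - j) >= 2
    )
    return MisclassificationReport(
        matrix=M,
        total=float(upper + lower),
        overestimated=float(upper),
        underestimated=float(lower),
        non_adjacent=float(far),
    )


def cross_model_cov(surfaces: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-cell coefficient of variation across ≥2 model surfaces:
    100 × sample SD / mean. Cells with zero mean are flagged undefined
    (NaN). Returns grid_id, cov, with summary stats in ``.attrs``."""
    if len(surfaces) < 2:
        raise ValueError("need at least 2 surfaces")
    mat, index = _stack_surfaces(surfaces)
    mean = mat.mean(axis=1)
    sd = mat.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = np.where(mean != 0, 100.0 * sd / mean, np.nan)
    n_undef = int(np.isnan(cov).sum())
    if n_undef:
        logger.warning("%d cell(s) with zero mean: COV undefined", n_undef)
    out = pd.DataFrame({"grid_id": index, "cov": cov})
    finite = cov[~np.isnan(cov)]
    out.attrs["summary"] = {
        "min": float(np.min(finite)),
        "median": float(np.median(finite)),
        "max": float(np.max(finite)),
    }
    return out


def cross_model_correlation(surfaces: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Pairwise Pearson correlation matrix of model surfaces (diagonal 1);
    constant surfaces get NaN rows/columns with a warning."""
    if len(surfaces) < 2:
        raise ValueError("need at least 2 surfaces")
    mat, _ = _stack_surfaces(surfaces)
    names = list(surfaces)
    k = len(names)
    out = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            if np.var(mat[:, i]) == 0 or np.var(mat[:, j]) == 0:
                logger.warning(
                    "constant surface among (%s, %s): correlation undefined",
                    names[i],
                    names[j],
                )
                out[i, j] = out[j, i] = np.nan
            else:
                out[i, j] = out[j, i] = np.corrcoef(mat[:, i], mat[:, j])[0, 1]
    return pd.DataFrame(out, index=names, columns=names)


def _stack_surfaces(surfaces: dict[str, pd.DataFrame]):
    names = list(surfaces)
    base = surfaces[names[0]].set_index("grid_id")["prediction"]
    cols = [base]
    for name in names[1:]:
        s = surfaces[name].set_index("grid_id")["prediction"]
        if not s.index.equals(base.index):
            raise ValueError(f"surface {name!r} covers a different grid")
        cols.append(s)
    return np.column_stack([c.to_numpy(dtype=float) for c in cols]), base.index
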