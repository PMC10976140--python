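"""Simple diagnostic figures: variogram fit and observed-vs-predicted."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from lurok.kriging import VariogramModel


def plot_variogram(
    emp: pd.DataFrame, model: VariogramModel | None, path: str | Path
) -> None:
    """Empirical semivariogram points (sized by pair count) with the fitted
    model curve."""
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(emp["lag"], emp["gamma"], s=10 + emp["n_pairs"], alpha=0.7,
               label="empirical")
    if model is not None:
        h = np.linspace(0, emp["lag"].max() * 1.05, 200)
        ax.plot(h, model(h), "r-", label=f"{model.family} fit")
    ax.set_xlabel("lag h (m)")
    ax.set_ylabel("semivariance γ(h) ((µg/m³)²)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_obs_vs_pred(predictions: pd.DataFrame, path: str | Path) -> None:
    """Observed vs LOOCV-predicted scatter with the 1:1 line, one panel per
    (family, kriging) combination present."""
    groups = list(predictions.groupby(["family", "kriging"]))
    n = len(groups)
    ncol = min(n, 3)
    nrow = (n + ncol - 1) // ncol
    fig, axes = plt.subplots(nrow, ncol, figsize=(4 * ncol, 3.5 * nrow),
                             squeeze=False)
    lo = min(predictions["observed"].min(), predictions["predicted"].min())
    hi = max(predictions["observed"].max(), predictions["predicted"].max())
    for ax, ((family, ok), grp) in zip(axes.ravel(), groups):
        ax.scatter(grp["observed"], grp["predicted"], s=15, alpha=0.7)
        ax.plot([lo, hi], [lo, hi], "k--", lw=1)
        ax.set_title(f"{family}{'-OK' if ok else ''}")
        ax.set_xlabel("observed (µg/m³)")
        ax.set_ylabel("LOOCV predicted (µg/m³)")
    for ax in axes.ravel()[n:]:
        ax.axis("off")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
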