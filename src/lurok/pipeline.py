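"""End-to-end orchestration: simulate → aggregate → fit → cv → predict → compare.

A single RunConfig (loadable from YAML) drives every stage; outputs are CSV/
JSON files in the run directory plus a manifest recording the config, the
seed, and a SHA-256 checksum of every produced file, so repeated seeded runs
can be verified byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from lurok import synthetic, temporal
from lurok.models import PLSSpec, RFSpec, SLRSpec
from lurok.kriging import fit_hybrid
from lurok.validation import loocv
from lurok.exposure import (
    predict_surface,
    population_weighted_mean,
    quartile_classify,
    misclassification,
    cross_model_cov,
    cross_model_correlation,
)

logger = logging.getLogger(__name__)

FAMILIES_DEFAULT = ("PLS", "RF", "SLR")


@dataclass
class RunConfig:
    """Everything one pipeline run needs; round-trips through YAML."""

    pollutant: str = "NO2"
    site_subset: str = "all"  # all | urban-only
    families: tuple[str, ...] = FAMILIES_DEFAULT
    kriging: bool = True  # fit both with and without OK when True
    seed: int = 0
    output_dir: str = "lurok_run"

    # simulation
    n_sites: int = 35
    n_years: int = 2
    start_year: int = 2015
    n_variables: int = 12
    n_signal: int = 4
    missing_rate: float = 0.15
    residual_sill: float = 9.0
    residual_range: float = 15_000.0
    nugget: float = 0.25
    noise_sd: float = 8.0
    seasonal_amplitude: float = 10.0

    # model specs
    pls_n_scores: int = 3
    rf_mtry: int = 50
    rf_ntree: int = 500
    rf_node_size: int = 5
    slr_r2_gain: float = 0.1
    slr_vif_max: float = 3.0
    slr_enforce_sign: bool = True
    variogram_family: str = "exponential"
    utc_offset_hours: int = 8

    def __post_init__(self):
        if self.site_subset not in ("all", "urban-only"):
            raise ValueError("site_subset must be 'all' or 'urban-only'")
        self.families = tuple(f.upper() for f in self.families)
        for f in self.families:
            if f not in FAMILIES_DEFAULT:
                raise ValueError(f"unknown family {f!r}")

    def sim_config(self) -> synthetic.SimulationConfig:
        return synthetic.SimulationConfig(
            n_sites=self.n_sites,
            n_years=self.n_years,
            start_year=self.start_year,
            pollutant=self.pollutant,
            n_variables=self.n_variables,
            n_signal=self.n_signal,
            missing_rate=self.missing_rate,
            residual_sill=self.residual_sill,
            residual_range=self.residual_range,
            nugget=self.nugget,
            noise_sd=self.noise_sd,
            seasonal_amplitude=self.seasonal_amplitude,
            seed=self.seed,
        )

    def lur_spec(self, family: str):
        if family == "PLS":
            return PLSSpec(self.pls_n_scores)
        if family == "RF":
            return RFSpec(self.rf_mtry, self.rf_ntree, self.rf_node_size, self.seed)
        return SLRSpec(self.slr_r2_gain, self.slr_vif_max, self.slr_enforce_sign)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["families"] = list(d["families"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _subset_sites(network: pd.DataFrame, grid: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Urban-only mode keeps urban and traffic sites plus any other site
    whose coordinates fall inside the prediction-grid bounding box."""
    if mode == "all":
        return network
    in_bounds = (
        network["x"].between(grid["x"].min(), grid["x"].max())
        & network["y"].between(grid["y"].min(), grid["y"].max())
    )
    keep = network["site_type"].isin(["urban", "traffic"]) | in_bounds
    return network[keep].reset_index(drop=True)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the run manifest (also written to
    ``manifest.json`` in the output directory)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": json.loads(json.dumps(asdict(config), default=list)),
        "seed": config.seed,
        "stages": [],
        "files": {},
    }

    def record(stage: str, **info):
        manifest["stages"].append({"stage": stage, **info})
        logger.info("stage %s done", stage)

    def save_csv(name: str, frame: pd.DataFrame, **kw) -> Path:
        p = out / name
        frame.to_csv(p, index=False, **kw)
        manifest["files"][name] = _sha256(p)
        return p

    def save_json(name: str, obj) -> Path:
        p = out / name
        p.write_text(json.dumps(obj, indent=2, sort_keys=True))
        manifest["files"][name] = _sha256(p)
        return p

    try:
        # --- simulate -----------------------------------------------------
        sim = config.sim_config()
        fields = synthetic.CovariateFieldSet(sim)
        network = synthetic.generate_network(sim)
        X_all, meta = synthetic.generate_covariates(network, sim, fields=fields)
        hourly = synthetic.generate_concentrations(network, X_all, sim)
        grid = synthetic.generate_population_grid(sim, fields=fields)
        network = _subset_sites(network, grid, config.site_subset)
        X = X_all.loc[network["site_id"]]
        synthetic.write_dataset(out, network, hourly, X, meta, grid)
        for f in ("sites.csv", "hourly.csv", "covariates.csv", "variable_meta.csv", "grid.csv"):
            manifest["files"][f] = _sha256(out / f)
        record("simulate", n_sites=len(network), n_hourly_rows=len(hourly),
               n_grid_cells=len(grid), site_subset=config.site_subset)

        # --- aggregate ----------------------------------------------------
        hourly = hourly[hourly["site_id"].isin(network["site_id"])]
        years = list(range(config.start_year, config.start_year + config.n_years))
        aggregates = temporal.aggregate_all(
            hourly, years=years, utc_offset_hours=config.utc_offset_hours
        )
        save_csv("aggregates.csv", aggregates)
        wide = temporal.annual_wide(aggregates).reindex(network["site_id"])
        periods = [str(y) for y in years] + [f"{min(years)}-{max(years)}"]
        record("aggregate", periods=periods,
               n_available={p: int(wide[p].notna().sum()) for p in periods if p in wide})

        # --- cv -----------------------------------------------------------
        coords = network[["x", "y"]].to_numpy(dtype=float)
        signs = meta["expected_sign"].to_dict()
        metric_rows, pred_rows = [], []
        for period in periods:
            y = wide[period] if period in wide else pd.Series(np.nan, index=wide.index)
            if y.notna().sum() < 5:
                logger.warning("period %s: too few sites with data; skipped", period)
                continue
            for family in config.families:
                spec = config.lur_spec(family)
                if config.kriging:
                    cv_ok, cv_plain = loocv(
                        family, X, y, coords, lur_spec=spec, expected_sign=signs,
                        kriging=True, variogram_family=config.variogram_family,
                        return_lur_only=True,
                    )
                    results = [(False, cv_plain), (True, cv_ok)]
                else:
                    results = [(False, loocv(family, X, y, coords, lur_spec=spec,
                                             expected_sign=signs, kriging=False))]
                for with_ok, cv in results:
                    s = cv.summary()
                    metric_rows.append(
                        {"pollutant": config.pollutant, "period": period,
                         "family": family, "kriging": with_ok, **s}
                    )
                    p = cv.predictions.copy()
                    p.insert(1, "period", period)
                    p["family"] = family
                    p["kriging"] = with_ok
                    pred_rows.append(p)
        cv_metrics = pd.DataFrame(metric_rows)
        save_csv("cv_metrics.csv", cv_metrics, float_format="%.10g")
        save_csv("cv_predictions.csv", pd.concat(pred_rows, ignore_index=True),
                 float_format="%.10g")
        record("cv", n_rows=len(cv_metrics))

        # --- fit on LTM + predict surfaces ---------------------------------
        ltm_key = periods[-1]
        y_ltm = wide[ltm_key]
        ok_mask = y_ltm.notna().to_numpy()
        surfaces: dict[str, pd.DataFrame] = {}
        pee: dict[str, float] = {}
        for family in config.families:
            model = fit_hybrid(
                family, X.loc[ok_mask], y_ltm[ok_mask].to_numpy(), coords[ok_mask],
                lur_spec=config.lur_spec(family), expected_sign=signs,
                kriging=config.kriging, variogram_family=config.variogram_family,
            )
            tag = f"{family}-OK" if config.kriging else family
            surf = predict_surface(model, grid)
            surfaces[tag] = surf
            pee[tag] = population_weighted_mean(surf, grid)
            save_csv(f"surface_{tag}.csv", surf, float_format="%.10g")
            if model.kriging_enabled:
                save_json(
                    f"variogram_{tag}.json",
                    {"family": model.variogram.family,
                     "nugget": model.variogram.nugget,
                     "partial_sill": model.variogram.partial_sill,
                     "range_m": model.variogram.range_},
                )
        save_json("pee.json", pee)
        record("predict", models=list(surfaces), period=ltm_key)

        # --- compare -------------------------------------------------------
        if len(surfaces) >= 2:
            classes = {
                tag: quartile_classify(surf, grid) for tag, surf in surfaces.items()
            }
            tags = list(surfaces)
            mis = {}
            for i in range(len(tags)):
                for j in range(i + 1, len(tags)):
                    rep = misclassification(classes[tags[i]], classes[tags[j]], grid)
                    mis[f"{tags[i]} vs {tags[j]}"] = rep.to_dict()
            save_json("misclassification.json", mis)
            cov = cross_model_cov(surfaces)
            save_csv("cov.csv", cov, float_format="%.10g")
            save_json("cov_summary.json", cov.attrs["summary"])
            corr = cross_model_correlation(surfaces)
            p = out / "correlation.csv"
            corr.to_csv(p, float_format="%.10g")
            manifest["files"]["correlation.csv"] = _sha256(p)
            record("compare", n_pairs=len(mis))
    except Exception as exc:
        manifest["failure"] = repr(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
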