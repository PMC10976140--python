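"""Synthetic monitoring networks, covariates, concentrations and grids.

Everything downstream (temporal screening, the three LUR families, residual
kriging, LOOCV, exposure assessment) is exercised on data generated here.
The generator emulates the statistical structure of an urban monitoring
network: a handful of fixed sites of four types (background / traffic /
urban / suburban), smooth spatially correlated geographic covariates, a
concentration field that is linear in a covariate subset plus a spatially
autocorrelated residual, a seasonal cycle, measurement noise, and realistic
missingness (random gaps plus long contiguous outages).

Coordinates live in an abstract planar projection in meters; no real CRS is
attached.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

SITE_TYPES = ("background", "traffic", "urban", "suburban")

# Names for the smooth covariate fields, echoing the kinds of geographic
# variables LUR studies extract from GIS layers (population, roads, POI,
# NDVI, land use, topography). They are abstract fields with the same
# statistical role, not real GIS extractions.
_FIELD_NAMES = [
    "pop_density",
    "major_road_length",
    "ndvi_summer",
    "dist_traffic",
    "poi_industry",
    "impervious_frac",
    "grassland_frac",
    "dist_railway",
    "elevation",
    "poi_restaurants",
    "shrubland_frac",
    "dist_airport",
    "ndvi_p75",
    "poi_bus_stops",
    "water_frac",
    "forest_frac",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults describe the reference scenario: a 35-site network observed
    hourly over two calendar years on an 80 km square domain, 12 geographic
    covariates (10 smooth random fields + 2 coordinate variables) of which 4
    carry signal, a spatially autocorrelated residual field, an annual
    sinusoidal seasonal cycle and 15% missing hours.
    """

    n_sites: int = 35
    n_years: int = 2
    start_year: int = 2015
    pollutant: str = "NO2"

    n_variables: int = 12
    n_signal: int = 4
    beta: np.ndarray | None = None  # per-covariate true coefficients
    intercept: float = 40.0  # µg/m³

    residual_sill: float = 9.0  # (µg/m³)² spatial residual variance
    residual_range: float = 15_000.0  # m, exponential covariance range
    nugget: float = 0.25  # (µg/m³)² site-level micro-scale variance
    noise_sd: float = 8.0  # µg/m³ iid hourly noise
    seasonal_amplitude: float = 10.0  # µg/m³

    missing_rate: float = 0.15
    domain_size: float = 80_000.0  # m, side of the square study domain
    covariate_length_scale: float = 20_000.0  # m, smoothness of fields
    seed: int = 0

    def __post_init__(self) -> None:
        if self.residual_sill < 0 or self.nugget < 0 or self.noise_sd < 0:
            raise ValueError("variance parameters must be nonnegative")
        if self.residual_range <= 0:
            raise ValueError("residual_range must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_variables < 2:
            raise ValueError("n_variables must be at least 2")
        if self.beta is not None:
            self.beta = np.asarray(self.beta, dtype=float)
            if self.beta.shape != (self.n_variables,):
                raise ValueError(
                    f"beta must have length n_variables={self.n_variables}"
                )

    def true_beta(self) -> np.ndarray:
        """Per-covariate coefficients; default assigns alternating-sign
        betas to the first ``n_signal`` smooth fields."""
        if self.beta is not None:
            return self.beta
        beta = np.zeros(self.n_variables)
        base = [8.0, -6.0, 5.0, -4.0, 3.0, -2.5, 2.0, -1.5]
        for j in range(min(self.n_signal, self.n_variables - 2)):
            beta[j] = base[j % len(base)] * (1 + j // len(base))
        return beta


# ---------------------------------------------------------------------------
# monitoring network


def _type_counts(n_sites: int) -> dict[str, int]:
    """Site counts per type; 35 sites reproduce the reference 1/7/14/13
    composition, other totals keep 1 background and split the rest 7:14:13."""
    if n_sites < 4:
        raise ValueError("n_sites must be >= 4 to represent all four types")
    if n_sites == 35:
        return {"background": 1, "traffic": 7, "urban": 14, "suburban": 13}
    rest = n_sites - 1
    traffic = max(1, round(rest * 7 / 34))
    urban = max(1, round(rest * 14 / 34))
    suburban = rest - traffic - urban
    while suburban < 1:  # reclaim from the largest bucket
        if urban >= traffic:
            urban -= 1
        else:
            traffic -= 1
        suburban = rest - traffic - urban
    return {
        "background": 1,
        "traffic": traffic,
        "urban": urban,
        "suburban": suburban,
    }


def generate_network(config: SimulationConfig) -> pd.DataFrame:
    """Generate a monitoring network as a DataFrame.

    Columns: ``site_id``, ``x``, ``y`` (meters, domain-centered), and
    ``site_type``. Urban and traffic sites cluster near the domain center,
    suburban sites sit on a peripheral ring, and the single background site
    lies farther from the center than any other site.
    """
    rng = np.random.default_rng(config.seed)
    counts = _type_counts(config.n_sites)
    half = config.domain_size / 2
    rows: list[tuple[str, float, float, str]] = []
    i = 0

    def add(x: float, y: float, stype: str) -> None:
        nonlocal i
        rows.append((f"site_{i:03d}", float(x), float(y), stype))
        i += 1

    # urban: Gaussian cluster at the center, clipped to a 15 km radius
    for _ in range(counts["urban"]):
        while True:
            x, y = rng.normal(0.0, 0.2 * half, size=2)
            if math.hypot(x, y) <= 0.375 * half:
                break
        add(x, y, "urban")
    # traffic: near-center ring (arterial roads radiate from the core)
    for _ in range(counts["traffic"]):
        r = rng.uniform(0.05, 0.45) * half
        th = rng.uniform(0, 2 * math.pi)
        add(r * math.cos(th), r * math.sin(th), "traffic")
    # suburban: peripheral ring
    for _ in range(counts["suburban"]):
        r = rng.uniform(0.55, 0.95) * half
        th = rng.uniform(0, 2 * math.pi)
        add(r * math.cos(th), r * math.sin(th), "suburban")
    # background: beyond every other site, random direction
    th = rng.uniform(0, 2 * math.pi)
    r = 1.1 * half
    add(r * math.cos(th), r * math.sin(th), "background")

    net = pd.DataFrame(rows, columns=["site_id", "x", "y", "site_type"])
    return net.sort_values("site_id", ignore_index=True)


# ---------------------------------------------------------------------------
# covariate fields


class CovariateFieldSet:
    """A deterministic set of smooth spatial fields evaluable anywhere.

    Smooth fields are random-Fourier-feature approximations of Gaussian
    random fields (sum of cosines with Gaussian-distributed wavevectors),
    giving mean ~0, variance ~1 over the domain. The last two variables are
    scaled coordinates (x, y), mimicking the longitude/latitude covariates
    that LUR studies include.
    """

    def __init__(self, config: SimulationConfig):
        self.config = config
        n_fields = config.n_variables - 2  # last two are coordinates
        rng = np.random.default_rng(config.seed + 1_000_003)
        self.n_waves = 48
        scale = 2 * math.pi * config.covariate_length_scale
        # wavevectors ~ N(0, 1/(2π ℓ)²) per axis -> squared-exponential-like
        self._freqs = rng.normal(0.0, 1.0 / scale, size=(n_fields, self.n_waves, 2))
        self._phases = rng.uniform(0, 2 * math.pi, size=(n_fields, self.n_waves))
        names = list(_FIELD_NAMES)
        while len(names) < n_fields:
            names.append(f"field_{len(names):02d}")
        self.names = names[:n_fields] + ["coord_x", "coord_y"]
        beta = config.true_beta()
        self.beta = beta
        self.expected_sign = [
            "+" if b > 0 else "-" if b < 0 else "0" for b in beta
        ]

    def evaluate(self, x: np.ndarray, y: np.ndarray) -> pd.DataFrame:
        """Evaluate every field at coordinates (x, y) -> units × variables."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        pts = np.stack([x, y], axis=-1)  # (n, 2)
        # phase matrix: (n_fields, n, n_waves)
        arg = np.einsum("fwk,nk->fnw", self._freqs, pts) * 2 * math.pi
        vals = np.sqrt(2.0 / self.n_waves) * np.cos(arg + self._phases[:, None, :])
        fields = vals.sum(axis=2)  # (n_fields, n)
        half = self.config.domain_size / 2
        cols = list(fields) + [x / half, y / half]
        return pd.DataFrame(
            {name: col for name, col in zip(self.names, cols)}
        )

    def meta(self) -> pd.DataFrame:
        groups = ["field"] * (len(self.names) - 2) + ["coordinate"] * 2
        return pd.DataFrame(
            {
                "variable": self.names,
                "expected_sign": self.expected_sign,
                "group": groups,
                "beta": self.beta,
            }
        ).set_index("variable")


def generate_covariates(
    units: pd.DataFrame,
    config: SimulationConfig,
    fields: CovariateFieldSet | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluate the covariate fields at unit locations.

    ``units`` is any frame with ``x``/``y`` columns and a ``site_id`` or
    ``grid_id`` column. Returns ``(X, meta)``: a units × variables frame
    indexed by unit id, and per-variable metadata (expected_sign, group,
    true beta). The same ``config`` (seed) yields the same fields for sites
    and grid, so site and grid covariates are mutually consistent.
    """
    if fields is None:
        fields = CovariateFieldSet(config)
    id_col = "site_id" if "site_id" in units.columns else "grid_id"
    X = fields.evaluate(units["x"].to_numpy(), units["y"].to_numpy())
    X.index = pd.Index(units[id_col], name=id_col)
    return X, fields.meta()


# ---------------------------------------------------------------------------
# concentrations


def spatial_residual(
    coords: np.ndarray, sill: float, rng_m: float, nugget: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw a zero-mean Gaussian field with exponential covariance
    C(h) = sill·exp(−h/range) (+ nugget on the diagonal) at ``coords`` via
    Cholesky factorization."""
    n = len(coords)
    if sill == 0 and nugget == 0:
        return np.zeros(n)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    cov = sill * np.exp(-d / rng_m) + nugget * np.eye(n)
    cov[np.diag_indices_from(cov)] += 1e-10 * max(sill + nugget, 1.0)
    L = np.linalg.cholesky(cov)
    return L @ rng.standard_normal(n)


def _missing_mask(
    n_hours: int, n_sites: int, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Boolean mask (hours × sites), True = observation removed. Half the
    budget is spent on contiguous block outages (whole weeks or months) so
    the completeness filters see both short and long gaps."""
    mask = np.zeros((n_hours, n_sites), dtype=bool)
    if rate == 0:
        return mask
    block_budget = rate / 2.0
    for j in range(n_sites):
        removed = 0
        target = block_budget * n_hours
        while removed < target:
            length = int(rng.choice([7 * 24, 30 * 24]))
            start = int(rng.integers(0, max(1, n_hours - length)))
            mask[start : start + length, j] = True
            removed = int(mask[:, j].sum())
    # top up with MCAR to the overall rate
    current = mask.mean()
    if current < rate:
        p = (rate - current) / (1 - current)
        mask |= rng.random((n_hours, n_sites)) < p
    return mask


def generate_concentrations(
    network: pd.DataFrame,
    covariates: pd.DataFrame,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Simulate hourly concentrations at every site.

    value(site, t) = intercept + X·β + S(site) + seasonal(t) + ε(t), floored
    at 0, where S is the spatially autocorrelated residual field and
    seasonal is a 1-year sinusoid. A ``missing_rate`` fraction of site-hours
    is removed (mixture of random gaps and contiguous block outages).
    Returns a long frame: site_id, timestamp (UTC, hourly), pollutant, value;
    missing hours are absent as rows.
    """
    if not network["site_id"].is_unique:
        raise ValueError("site_ids must be unique")
    if not covariates.index.equals(pd.Index(network["site_id"], name=covariates.index.name)):
        raise ValueError("covariates must be aligned to network sites (same ids, same order)")
    rng = np.random.default_rng(config.seed + 2_000_003)
    coords = network[["x", "y"]].to_numpy()
    beta = config.true_beta()
    site_mean = (
        config.intercept
        + covariates.to_numpy() @ beta
        + spatial_residual(
            coords, config.residual_sill, config.residual_range, config.nugget, rng
        )
    )

    times = pd.date_range(
        start=f"{config.start_year}-01-01",
        end=f"{config.start_year + config.n_years}-01-01",
        freq="h",
        tz="UTC",
        inclusive="left",
    )
    n_hours = len(times)
    hours_per_year = 365.25 * 24
    seasonal = config.seasonal_amplitude * np.sin(
        2 * math.pi * np.arange(n_hours) / hours_per_year
    )
    values = (
        site_mean[None, :]
        + seasonal[:, None]
        + rng.standard_normal((n_hours, len(site_mean))) * config.noise_sd
    )
    np.maximum(values, 0.0, out=values)

    mask = _missing_mask(n_hours, len(site_mean), config.missing_rate, rng)
    values[mask] = np.nan

    long = pd.DataFrame(values, index=times, columns=network["site_id"])
    long = (
        long.stack(future_stack=True)
        .rename("value")
        .reset_index()
        .rename(columns={"level_0": "timestamp", "level_1": "site_id"})
    )
    long.columns = ["timestamp", "site_id", "value"]
    long = long.dropna(subset=["value"]).reset_index(drop=True)
    long["pollutant"] = config.pollutant
    return long[["site_id", "timestamp", "pollutant", "value"]]


# ---------------------------------------------------------------------------
# population grid


def generate_population_grid(
    config: SimulationConfig,
    n_cells: int = 3301,
    cell_size: float = 1000.0,
    density_bounds: tuple[float, float] = (211.0, 32_097.0),
    target_total: float = 15.94e6,
    fields: CovariateFieldSet | None = None,
) -> pd.DataFrame:
    """Generate the urban prediction grid with population and covariates.

    A near-square lattice of 1-km cells centered on the domain, trimmed to
    exactly ``n_cells`` by dropping the cells farthest from the center.
    Population density is center-peaked (exponential decay with lognormal
    texture), clipped to ``density_bounds`` and rescaled so the total equals
    ``target_total``. Covariate columns use the same fields as the sites.
    """
    side = math.ceil(math.sqrt(n_cells))
    nx, ny = side, side
    while nx * (ny - 1) >= n_cells:
        ny -= 1
    xs = (np.arange(nx) - (nx - 1) / 2) * cell_size
    ys = (np.arange(ny) - (ny - 1) / 2) * cell_size
    gx, gy = np.meshgrid(xs, ys)
    gx, gy = gx.ravel(), gy.ravel()
    dist = np.hypot(gx, gy)
    keep = np.argsort(dist, kind="stable")[:n_cells]
    keep.sort()
    gx, gy, dist = gx[keep], gy[keep], dist[keep]

    rng = np.random.default_rng(config.seed + 3_000_003)
    raw = np.exp(-dist / 12_000.0) * rng.lognormal(0.0, 0.45, size=n_cells)
    lo, hi = density_bounds
    pop = raw / raw.mean() * (target_total / n_cells)
    for _ in range(200):
        pop = np.clip(pop, lo, hi)
        total = pop.sum()
        if abs(total - target_total) <= 1e-9 * target_total:
            break
        free = (pop > lo) & (pop < hi)
        if not free.any():
            pop *= target_total / total
            break
        pop[free] += (target_total - total) / free.sum()
    pop = np.clip(pop, lo, hi)

    grid = pd.DataFrame(
        {
            "grid_id": [f"grid_{k:04d}" for k in range(n_cells)],
            "x": gx,
            "y": gy,
            "population": pop,
        }
    )
    X, _ = generate_covariates(grid, config, fields=fields)
    return pd.concat([grid.set_index("grid_id"), X], axis=1).reset_index()


# ---------------------------------------------------------------------------
# writers


def write_dataset(
    out_dir: str | Path,
    network: pd.DataFrame,
    hourly: pd.DataFrame,
    covariates: pd.DataFrame,
    meta: pd.DataFrame,
    grid: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write the standard CSV bundle (sites, hourly, covariates,
    variable_meta, grid) plus GeoJSON site/grid exports; returns the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["sites"] = out / "sites.csv"
    network.to_csv(paths["sites"], index=False)

    paths["hourly"] = out / "hourly.csv"
    h = hourly.copy()
    h["timestamp"] = pd.to_datetime(h["timestamp"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%SZ"
    )
    h.to_csv(paths["hourly"], index=False)

    paths["covariates"] = out / "covariates.csv"
    covariates.rename_axis("unit_id").to_csv(paths["covariates"])

    paths["variable_meta"] = out / "variable_meta.csv"
    m = meta.reset_index()[["variable", "expected_sign", "group"]]
    m["description"] = "synthetic geographic covariate field"
    m.to_csv(paths["variable_meta"], index=False)

    paths["sites_geojson"] = out / "sites.geojson"
    _write_point_geojson(paths["sites_geojson"], network, "site_id")

    if grid is not None:
        paths["grid"] = out / "grid.csv"
        grid.to_csv(paths["grid"], index=False)
        paths["grid_geojson"] = out / "grid.geojson"
        _write_point_geojson(paths["grid_geojson"], grid, "grid_id")
    return paths


def _write_point_geojson(path: Path, frame: pd.DataFrame, id_col: str) -> None:
    features = []
    prop_cols = [c for c in frame.columns if c not in ("x", "y")]
    for _, row in frame.iterrows():
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [row["x"], row["y"]]},
                "properties": {c: _jsonable(row[c]) for c in prop_cols},
            }
        )
    path.write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    return v
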