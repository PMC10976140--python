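"""Predict exposure over the 1-km population grid and quantify how much of
the population the three hybrid models place in different exposure
quartiles.

Quartile cutpoints are person-level: each person carries their grid cell's
predicted concentration and the 25/50/75% quantiles are taken over persons,
so a cell with a large population moves the cutpoints more than an empty
one.
"""

import numpy as np

from lurok import SimulationConfig, generate_covariates, generate_network
from lurok.exposure import (
    cross_model_correlation,
    cross_model_cov,
    misclassification,
    population_weighted_mean,
    predict_surface,
    quartile_classify,
)
from lurok.kriging import fit_hybrid
from lurok.models import RFSpec
from lurok.synthetic import (
    CovariateFieldSet,
    generate_concentrations,
    generate_population_grid,
)
from lurok.temporal import aggregate_all, annual_wide

cfg = SimulationConfig(seed=3, n_years=1)
fields = CovariateFieldSet(cfg)
network = generate_network(cfg)
X, meta = generate_covariates(network, cfg, fields=fields)
hourly = generate_concentrations(network, X, cfg)
y = annual_wide(aggregate_all(hourly))["2015"].reindex(X.index)
coords = network[["x", "y"]].to_numpy(float)
grid = generate_population_grid(cfg, fields=fields)
print(f"grid: {len(grid)} cells, total population "
      f"{grid['population'].sum() / 1e6:.2f} million")

surfaces, classes = {}, {}
for family in ("PLS", "RF", "SLR"):
    model = fit_hybrid(
        family, X, y.to_numpy(), coords,
        lur_spec=RFSpec(seed=0) if family == "RF" else None,
        expected_sign=meta["expected_sign"].to_dict(), kriging=True,
    )
    tag = f"{family}-OK"
    surfaces[tag] = predict_surface(model, grid)
    classes[tag] = quartile_classify(surfaces[tag], grid)
    pee = population_weighted_mean(surfaces[tag], grid)
    print(f"{tag}: population-weighted exposure estimate = {pee:.2f} µg/m³")

print("\npairwise correlation of surfaces:")
print(cross_model_correlation(surfaces).round(3))
cov = cross_model_cov(surfaces)
print("per-cell COV across models (%):",
      {k: round(v, 2) for k, v in cov.attrs["summary"].items()})

print("\npopulation share classified into different quartiles:")
tags = list(surfaces)
for i in range(len(tags)):
    for j in range(i + 1, len(tags)):
        rep = misclassification(classes[tags[i]], classes[tags[j]], grid)
        print(f"  {tags[i]} vs {tags[j]}: total {rep.total:.2f}% "
              f"(non-adjacent {rep.non_adjacent:.2f}%)")
# A pair of models can correlate strongly over the grid yet still assign
# 10-20% of the population to different exposure quartiles — the
# misclassification an epidemiological study inherits by picking one model.
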