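# pmcal

Spatial calibration and mapping of dense low-cost PM2.5 sensor networks.

Low-cost optical PM2.5 sensors (light-scattering particle counters) are
deployed by the thousands in community networks, but their readings are
biased relative to reference-grade regulatory monitors — and the bias
varies with location, driven by humidity, aerosol composition and the
local environment. A single linear correction fitted to the whole network
leaves large regional errors. `pmcal` is a toolkit for researchers and
air-quality agencies who want to correct a dense sensor network against a
sparse regulatory network **locally**, for one synchronized time slice,
and then map the corrected concentrations.

## Method

1. **Collocation.** Each regulatory station *i* is paired with its nearest
   low-cost sensor (planar Euclidean distance); pairs farther than 2 km
   apart are excluded. This yields *n* training records
   (Y_i, x_i, u_i, v_i): reference reading, sensor reading, and station
   coordinates in meters.

2. **Global (nonspatial) calibration** — ordinary least squares:

       E(Y_i | X_i) = β₀ + Σ_b β_b x_bi

   one coefficient set for the entire network (by default B = 1, the
   sensor PM2.5; covariates such as relative humidity can be added).

3. **Spatial calibration** — a kernel-weighted varying-coefficient model
   (geographically weighted regression). At any location (u, v),

       β̂(u, v) = [Xᵀ W(u, v) X]⁻¹ Xᵀ W(u, v) Y,
       W_jj = exp(−d_j² / b²),

   where d_j is the distance from (u, v) to training pair j and b is the
   kernel bandwidth, chosen by leave-one-out cross-validation. Every
   sensor gets its own coefficient set, solved at its own coordinate.

4. **Mapping.** Calibrated sensor values are gridded by inverse-distance
   weighting (power 2, 2 km cells) and the map is scored against the
   regulatory readings (RMSE, R²).

A synthetic-network generator with a closed-form truth field (Gaussian
plumes) and smooth multiplicative/additive bias surfaces makes every
stage testable with known ground truth.

## Worked example

```python
import numpy as np
from pmcal import (isolated_station_scenario, generate,
                   nearest_neighbor_pairs, filter_pairs, fit_global,
                   fit_spatial, select_bandwidth, loo_rmse_global,
                   loo_rmse_spatial, calibrate, make_grid,
                   idw_interpolate, evaluate_map)

sensors, stations, truth = generate(isolated_station_scenario(seed=1))
pairs = filter_pairs(nearest_neighbor_pairs(stations, sensors), 2000.0)
print(pairs.n, pairs.n_excluded)          # 69 7

bw = select_bandwidth(pairs)
print(round(bw))                          # 23475
print(round(loo_rmse_global(pairs), 2),   # 7.19
      round(loo_rmse_spatial(pairs, bw), 2))   # 4.57

glob, spat = fit_global(pairs), fit_spatial(pairs, bw)
spec = make_grid(sensors, resolution=2000.0)
for model in (glob, spat):
    field = idw_interpolate(calibrate(model, sensors), spec)
    print(round(evaluate_map(field, stations).rmse, 2))
# 7.06  (global map)
# 4.92  (spatial map)
```

Of the 76 stations, 7 sit farther than 2 km from any sensor and are
excluded; 69 collocated pairs train the models. Cross-validation selects
a ~23 km kernel bandwidth. The spatially varying model predicts held-out
stations with 4.57 µg/m³ error versus 7.19 µg/m³ for the single global
line, and the 2 km IDW map built from spatially calibrated sensors
misses the reference readings by 4.92 µg/m³ versus 7.06 µg/m³ — the
spatial model absorbs the location-dependent sensor bias that a global
fit cannot.

The same pipeline runs from the shell:

```sh
pmcal run-all --seed 1 --out out/          # synthetic snapshot end-to-end
pmcal run-all --config myrun.yaml          # your own sensor/station CSVs
```

producing `pairs.csv`, both model JSONs, residual tables, `map_*.asc`
(ESRI ASCII) / `map_*.csv` grids and JSON reports with the numbers above.

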