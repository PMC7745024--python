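"""Pipeline stages: simulate → collocate → calibrate → map.

Each stage reads its inputs from, and writes its artifacts into, the
configured output directory, together with a machine-readable manifest
(config echo, input hashes, record counts, selected bandwidth, …).  All
numeric output is deterministic given config + seed; no wall-clock state
is written, so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import __version__
from .calibration import (
    calibrate,
    default_bandwidth_candidates,
    fit_global,
    fit_spatial,
    loo_rmse_global,
    loo_rmse_spatial,
    select_bandwidth,
    GlobalCalibration,
    SpatialCalibration,
)
from .collocation import (
    CollocatedPairs,
    filter_pairs,
    mean_pair_distance,
    nearest_neighbor_pairs,
)
from .config import RunConfig
from .diagnostics import distribution_summary, pearson_correlation, residual_report
from .errors import ConfigurationError
from .io import ObservationSet, read_observations, write_observations
from .mapping import evaluate_map, idw_interpolate, make_grid
from . import synthetic

logger = logging.getLogger(__name__)

_PRESETS = {
    "default": synthetic.default_scenario,
    "homogeneous": synthetic.homogeneous_scenario,
    "linear_slope": synthetic.linear_slope_scenario,
    "exclusion": synthetic.isolated_station_scenario,
}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_manifest(cfg: RunConfig, stage: str, payload: dict,
                    inputs: list[Path] = ()) -> None:
    doc = {
        "stage": stage,
        "pmcal_version": __version__,
        "seed": cfg.seed,
        "config": cfg.to_dict(),
        "inputs": {str(p): _sha256(Path(p)) for p in inputs},
        **payload,
    }
    out = cfg.out_dir / f"manifest_{stage}.json"
    with open(out, "w") as fh:
        json.dump(doc, fh, indent=2)


def build_scenario(cfg: RunConfig) -> synthetic.SyntheticScenario:
    preset = _PRESETS.get(cfg.synthetic.preset)
    if preset is None:
        raise ConfigurationError(
            f"unknown synthetic preset {cfg.synthetic.preset!r}; "
            f"choose from {sorted(_PRESETS)}"
        )
    sc = preset(seed=cfg.seed)
    if cfg.synthetic.overrides:
        valid = {f.name for f in dataclasses.fields(sc)}
        bad = set(cfg.synthetic.overrides) - valid
        if bad:
            raise ConfigurationError(f"unknown scenario override(s) {sorted(bad)}")
        sc = dataclasses.replace(sc, **cfg.synthetic.overrides)
    return sc


def cmd_simulate(cfg: RunConfig) -> dict:
    """Generate the synthetic networks and write them as CSV."""
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    sc = build_scenario(cfg)
    sensors, stations, truth = synthetic.generate(sc)
    write_observations(sensors, cfg.sensors_path)
    write_observations(stations, cfg.stations_path)
    tframe = sensors.frame[["id", "u", "v"]].copy()
    tframe["truth"] = truth["sensor_truth"]
    tframe.to_csv(cfg.out_dir / "sensor_truth.csv", index=False)
    sc.to_json(cfg.out_dir / "scenario.json")
    payload = {"n_sensors": sensors.n, "n_stations": stations.n}
    _write_manifest(cfg, "simulate", payload)
    return payload


def _read_networks(cfg: RunConfig) -> tuple[ObservationSet, ObservationSet]:
    sensors = read_observations(cfg.sensors_path, network_kind="low_cost",
                                column_map={"u": "u", "v": "v"})
    stations = read_observations(cfg.stations_path, network_kind="regulatory",
                                 column_map={"u": "u", "v": "v"})
    return sensors, stations


def cmd_collocate(cfg: RunConfig) -> dict:
    """Pair stations with nearest sensors and apply the distance filter."""
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    sensors, stations = _read_networks(cfg)
    raw = nearest_neighbor_pairs(stations, sensors,
                                 covariates=tuple(cfg.calibration.covariates))
    pairs = filter_pairs(raw, cfg.collocation.max_distance_m)
    pairs.to_csv(cfg.out_dir / "pairs.csv")
    payload = {
        "n_pairs": pairs.n,
        "n_excluded": pairs.n_excluded,
        "max_distance_m": cfg.collocation.max_distance_m,
        "mean_distance_before_m": mean_pair_distance(raw),
        "mean_distance_after_m": mean_pair_distance(pairs),
        "covariates": ["pm25", *cfg.calibration.covariates],
    }
    _write_manifest(cfg, "collocate", payload,
                    inputs=[cfg.sensors_path, cfg.stations_path])
    return payload


def _read_pairs(cfg: RunConfig) -> CollocatedPairs:
    return CollocatedPairs.from_csv(
        cfg.out_dir / "pairs.csv",
        covariate_names=("pm25", *cfg.calibration.covariates),
        max_distance=cfg.collocation.max_distance_m,
    )


def cmd_calibrate(cfg: RunConfig) -> dict:
    """Fit both calibration models, select the bandwidth, report residuals."""
    pairs = _read_pairs(cfg)
    eps = cfg.calibration.ridge_epsilon

    glob = fit_global(pairs)
    bw_cfg = cfg.calibration.bandwidth_m
    if bw_cfg == "auto":
        candidates = cfg.calibration.bandwidth_candidates
        bandwidth = select_bandwidth(pairs, candidates, ridge_epsilon=eps)
    else:
        bandwidth = float(bw_cfg)
    spat = fit_spatial(pairs, bandwidth, ridge_epsilon=eps)

    X = pairs.X
    yhat_global = glob.predict(X)
    beta = spat.local_coefficients
    yhat_spatial = beta[:, 0] + np.einsum("nb,nb->n", X, beta[:, 1:])
    rep_global = residual_report(pairs, yhat_global)
    rep_spatial = residual_report(pairs, yhat_spatial)
    rep_raw = residual_report(pairs, X[:, 0])  # uncalibrated sensor readings

    glob.to_json(cfg.out_dir / "model_global.json")
    spat.to_json(cfg.out_dir / "model_spatial.json")
    rep_global.to_frame().to_csv(cfg.out_dir / "residuals_global.csv", index=False)
    rep_spatial.to_frame().to_csv(cfg.out_dir / "residuals_spatial.csv", index=False)

    payload = {
        "bandwidth_m": bandwidth,
        "bandwidth_mode": "auto" if bw_cfg == "auto" else "fixed",
        "n_train": pairs.n,
        "global": {
            "beta": [float(b) for b in glob.beta],
            "r_squared_insample": rep_global.r_squared,
            "rmse_insample": rep_global.rmse,
            "rmse_loocv": loo_rmse_global(pairs),
        },
        "spatial": {
            "mean_intercept": float(beta[:, 0].mean()),
            "mean_slope": float(beta[:, 1].mean()),
            "r_squared_insample": rep_spatial.r_squared,
            "rmse_insample": rep_spatial.rmse,
            "rmse_loocv": loo_rmse_spatial(pairs, bandwidth, eps),
        },
        "raw": {
            "rmse": rep_raw.rmse,
            "pearson_r": pearson_correlation(X[:, 0], pairs.y),
        },
    }
    with open(cfg.out_dir / "calibration_report.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    _write_manifest(cfg, "calibrate", payload, inputs=[cfg.out_dir / "pairs.csv"])
    return payload


def cmd_map(cfg: RunConfig) -> dict:
    """Calibrate the full sensor network with both models, grid by IDW,
    and score both maps against the regulatory stations."""
    sensors, stations = _read_networks(cfg)
    glob = GlobalCalibration.from_json(cfg.out_dir / "model_global.json")
    spat = SpatialCalibration.from_json(cfg.out_dir / "model_spatial.json")
    m = cfg.mapping

    payload = {"resolution_m": m.resolution_m, "power": m.power, "models": {}}
    spec = make_grid(sensors, m.resolution_m, m.padding_m)
    for name, model in (("global", glob), ("spatial", spat)):
        calibrated = calibrate(model, sensors)
        field = idw_interpolate(calibrated, spec, power=m.power,
                                max_radius=m.max_radius_m)
        field.to_asc(cfg.out_dir / f"map_{name}.asc")
        field.to_csv(cfg.out_dir / f"map_{name}.csv")
        ev_grid = evaluate_map(field, stations, mode="grid_lookup")
        ev_loo = evaluate_map(None, stations, mode="loo_idw",
                              points=calibrated, power=m.power)
        summ = distribution_summary(calibrated)
        payload["models"][name] = {
            "rmse_grid_lookup": ev_grid.rmse,
            "rmse_loo_idw": ev_loo.rmse,
            "n_stations_excluded": ev_grid.n_excluded,
            "calibrated_mean": summ.mean,
            "calibrated_sd": summ.sd,
        }
    g = payload["models"]["global"]["rmse_loo_idw"]
    s = payload["models"]["spatial"]["rmse_loo_idw"]
    payload["rmse_ratio_spatial_over_global"] = s / g
    payload["rmse_reduction_percent"] = 100.0 * (1 - s / g)
    with open(cfg.out_dir / "mapping_report.json", "w") as fh:
        json.dump(payload, fh, indent=2)
    _write_manifest(cfg, "map", payload,
                    inputs=[cfg.sensors_path, cfg.stations_path,
                            cfg.out_dir / "model_global.json",
                            cfg.out_dir / "model_spatial.json"])
    return payload


def cmd_run_all(cfg: RunConfig) -> dict:
    """simulate (if configured) → collocate → calibrate → map."""
    results = {}
    if cfg.synthetic is not None and not (cfg.sensors_path.exists()
                                          and cfg.stations_path.exists()):
        results["simulate"] = cmd_simulate(cfg)
    results["collocate"] = cmd_collocate(cfg)
    results["calibrate"] = cmd_calibrate(cfg)
    results["map"] = cmd_map(cfg)
    with open(cfg.out_dir / "run_report.json", "w") as fh:
        json.dump(results, fh, indent=2)
    return results
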