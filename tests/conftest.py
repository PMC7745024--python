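import numpy as np
import pandas as pd
import pytest

from pmcal import CollocatedPairs, ObservationSet


def make_obs(coords, pm25, kind="low_cost", ids=None, **covariates):
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    pm25 = np.asarray(pm25, dtype=float)
    if ids is None:
        prefix = "S" if kind == "low_cost" else "R"
        ids = [f"{prefix}{i:04d}" for i in range(len(pm25))]
    frame = pd.DataFrame({"id": ids, "u": coords[:, 0], "v": coords[:, 1],
                          "pm25": pm25})
    for name, vals in covariates.items():
        frame[name] = vals
    return ObservationSet(frame, network_kind=kind, crs_note="test planar meters")


def make_pairs(anchors, y, x, distances=None, extra_x=None):
    anchors = np.atleast_2d(np.asarray(anchors, dtype=float))
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(y)
    if distances is None:
        distances = np.full(n, 100.0)
    frame = pd.DataFrame({
        "station_id": [f"R{i:04d}" for i in range(n)],
        "sensor_id": [f"S{i:04d}" for i in range(n)],
        "distance": distances,
        "y": y,
        "x1": x,
    })
    names = ["pm25"]
    if extra_x is not None:
        for k, (name, vals) in enumerate(extra_x.items(), start=2):
            frame[f"x{k}"] = vals
            names.append(name)
    frame["u"] = anchors[:, 0]
    frame["v"] = anchors[:, 1]
    return CollocatedPairs(frame, covariate_names=tuple(names))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def wls_oracle(X, y, w):
    """Independent textbook estimator: (XᵀWX)⁻¹XᵀWY via explicit inverse."""
    W = np.diag(w)
    return np.linalg.inv(X.T @ W @ X) @ (X.T @ W @ y)
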