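"""Station–sensor collocation.

Each regulatory station is matched to its nearest low-cost sensor (planar
Euclidean distance, KD-tree), giving one calibration record per station:
the station's reference PM2.5 as response y and the sensor's reading (plus
any requested covariates) as the covariate vector x.  Pairs farther apart
than a distance threshold (default 2 km) are excluded from training.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import EmptyInputError, EmptyTrainingSetError
from .io import ObservationSet

logger = logging.getLogger(__name__)


@dataclass
class CollocatedPairs:
    """Matched (station, sensor) records forming the calibration set.

    ``frame`` columns: station_id, sensor_id, distance (m), y (regulatory
    µg/m³), x1 … xB (x1 is the raw low-cost PM2.5), u, v (anchor coordinate
    = the station's).  ``covariate_names`` names x1…xB in order.
    """

    frame: pd.DataFrame
    covariate_names: tuple[str, ...] = ("pm25",)
    max_distance: float = math.inf
    n_excluded: int = 0

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def B(self) -> int:
        return len(self.covariate_names)

    @property
    def y(self) -> np.ndarray:
        return self.frame["y"].to_numpy(dtype=float)

    @property
    def X(self) -> np.ndarray:
        """(n, B) covariate matrix, without intercept column."""
        cols = [f"x{b + 1}" for b in range(self.B)]
        return self.frame[cols].to_numpy(dtype=float)

    @property
    def anchors(self) -> np.ndarray:
        """(n, 2) anchor coordinates (u, v) in meters."""
        return self.frame[["u", "v"]].to_numpy(dtype=float)

    @property
    def distances(self) -> np.ndarray:
        return self.frame["distance"].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, covariate_names=("pm25",), max_distance=math.inf,
                 n_excluded=0) -> "CollocatedPairs":
        frame = pd.read_csv(path, dtype={"station_id": str, "sensor_id": str},
                            float_precision="round_trip")
        return cls(frame, tuple(covariate_names), max_distance, n_excluded)


def nearest_neighbor_pairs(
    stations: ObservationSet,
    sensors: ObservationSet,
    covariates: tuple[str, ...] = (),
) -> CollocatedPairs:
    """Pair every station with its nearest sensor (unfiltered).

    Ties in distance are broken toward the lexicographically smallest
    sensor id.  ``covariates`` names extra sensor columns (e.g. ``"rh"``)
    appended after the sensor PM2.5 as x2, x3, …; missing values become NaN
    and are dropped at fit time, not here.
    """
    if stations.n == 0 or sensors.n == 0:
        raise EmptyInputError("both station and sensor sets must be non-empty")
    tree = cKDTree(sensors.coords)
    dist, idx = tree.query(stations.coords)
    sensor_ids = sensors.frame["id"].to_numpy()
    # tie-break: any sensor within a relative hair of the minimum distance
    for i, (d, p) in enumerate(zip(dist, stations.coords)):
        cand = tree.query_ball_point(p, d * (1 + 1e-9) + 1e-9)
        if len(cand) > 1:
            best = min(cand, key=lambda j: sensor_ids[j])
            idx[i] = best
            dist[i] = float(np.hypot(*(sensors.coords[best] - p)))

    sens = sensors.frame.iloc[idx].reset_index(drop=True)
    frame = pd.DataFrame({
        "station_id": stations.frame["id"].to_numpy(),
        "sensor_id": sens["id"].to_numpy(),
        "distance": dist,
        "y": stations.pm25,
        "x1": sens["pm25"].to_numpy(dtype=float),
    })
    names = ["pm25"]
    for k, cov in enumerate(covariates, start=2):
        frame[f"x{k}"] = (
            sens[cov].to_numpy(dtype=float) if cov in sens.columns
            else np.full(len(sens), np.nan)
        )
        names.append(cov)
    frame["u"] = stations.coords[:, 0]
    frame["v"] = stations.coords[:, 1]
    return CollocatedPairs(frame, covariate_names=tuple(names))


def filter_pairs(pairs: CollocatedPairs, max_distance: float = 2000.0) -> CollocatedPairs:
    """Drop pairs separated by more than ``max_distance`` meters.

    Idempotent; the running exclusion count accumulates in ``n_excluded``.
    """
    if max_distance <= 0:
        raise ValueError(f"max_distance must be > 0, got {max_distance}")
    keep = pairs.frame["distance"] <= max_distance
    n_removed = int((~keep).sum())
    if keep.sum() == 0:
        raise EmptyTrainingSetError(
            f"all {pairs.n} pairs exceed max_distance={max_distance} m"
        )
    if n_removed:
        logger.info("filter_pairs: excluded %d pair(s) beyond %.0f m",
                    n_removed, max_distance)
    return replace(
        pairs,
        frame=pairs.frame[keep].reset_index(drop=True),
        max_distance=max_distance,
        n_excluded=pairs.n_excluded + n_removed,
    )


def mean_pair_distance(pairs: CollocatedPairs) -> float:
    """Arithmetic mean of pair separations, in meters."""
    if pairs.n == 0:
        raise EmptyInputError("no pairs")
    return float(pairs.distances.mean())
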