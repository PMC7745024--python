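"""Inverse-distance-weighted (IDW) gridding of point concentrations.

Calibrated sensor values are interpolated onto a regular planar grid
(default 2 km resolution) by inverse distance weighting with power 2:
each cell takes Σ w_j z_j / Σ w_j with w_j = d_j^(−power).  A cell whose
center coincides with a data point (d < 1 nm) takes that point's value
exactly, so the interpolant honors the data.  By construction every
estimate lies between the minimum and maximum observed value.

Map accuracy is scored against reference stations either by bilinear
lookup in the gridded field or by re-running IDW directly at each station
location from the point data.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator

from .errors import EmptyInputError
from .io import ObservationSet

logger = logging.getLogger(__name__)

#: distances below this (meters) count as "cell center on a data point"
COINCIDENT_TOL = 1e-9
#: cap on the floats held per distance-matrix chunk (~64 MB)
_CHUNK_FLOATS = 8_000_000


@dataclass
class GridSpec:
    """Regular grid geometry: lower-left *cell center*, square cells."""

    origin: tuple[float, float]     # (u0, v0) meters, lower-left cell center
    resolution: float               # meters per cell
    nx: int
    ny: int

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError(f"resolution must be > 0, got {self.resolution}")
        if self.nx < 1 or self.ny < 1:
            raise ValueError("nx and ny must be >= 1")

    @property
    def u_centers(self) -> np.ndarray:
        return self.origin[0] + self.resolution * np.arange(self.nx)

    @property
    def v_centers(self) -> np.ndarray:
        return self.origin[1] + self.resolution * np.arange(self.ny)


@dataclass
class GridField:
    """Gridded concentrations; ``mask`` flags cells with no estimate."""

    spec: GridSpec
    values: np.ndarray  # (ny, nx), µg/m³; row i ↔ v_centers[i]
    mask: np.ndarray    # (ny, nx) bool, True = no estimate

    def to_csv(self, path) -> None:
        uu, vv = np.meshgrid(self.spec.u_centers, self.spec.v_centers)
        frame = pd.DataFrame({
            "u": uu.ravel(), "v": vv.ravel(),
            "value": np.where(self.mask, np.nan, self.values).ravel(),
        })
        frame.to_csv(path, index=False)

    def to_asc(self, path, nodata: float = -9999.0) -> None:
        """ESRI ASCII grid; rows written north-to-south per the format."""
        vals = np.where(self.mask, nodata, self.values)
        with open(path, "w") as fh:
            fh.write(f"ncols {self.spec.nx}\n")
            fh.write(f"nrows {self.spec.ny}\n")
            fh.write(f"xllcenter {self.spec.origin[0]:.6f}\n")
            fh.write(f"yllcenter {self.spec.origin[1]:.6f}\n")
            fh.write(f"cellsize {self.spec.resolution:.6f}\n")
            fh.write(f"NODATA_value {nodata:.1f}\n")
            for row in vals[::-1]:
                fh.write(" ".join(format(x, ".6f") for x in row) + "\n")


def make_grid(points: ObservationSet, resolution: float = 2000.0,
              padding: float = 0.0) -> GridSpec:
    """Grid covering the bounding box of ``points`` expanded by ``padding``.

    Cell counts use a ceil-plus-one convention so the far edge of the
    (padded) box always falls on or inside the last cell center.
    """
    if points.n == 0:
        raise EmptyInputError("no points to grid")
    if resolution <= 0:
        raise ValueError(f"resolution must be > 0, got {resolution}")
    c = points.coords
    u0, v0 = c[:, 0].min() - padding, c[:, 1].min() - padding
    width = c[:, 0].max() + padding - u0
    height = c[:, 1].max() + padding - v0
    # tolerate float fuzz when the extent is an exact multiple of resolution
    nx = int(math.ceil(width / resolution - 1e-9)) + 1
    ny = int(math.ceil(height / resolution - 1e-9)) + 1
    return GridSpec(origin=(u0, v0), resolution=resolution, nx=nx, ny=ny)


def _idw_at(targets: np.ndarray, points: np.ndarray, values: np.ndarray,
            power: float, max_radius: float | None) -> tuple[np.ndarray, np.ndarray]:
    """IDW estimates and a no-estimate mask at arbitrary target coords."""
    est = np.empty(len(targets))
    mask = np.zeros(len(targets), dtype=bool)
    step = max(1, _CHUNK_FLOATS // max(len(points), 1))
    for s in range(0, len(targets), step):
        t = targets[s:s + step]
        d = np.hypot(t[:, 0, None] - points[None, :, 0],
                     t[:, 1, None] - points[None, :, 1])
        hit_i, hit_j = np.nonzero(d < COINCIDENT_TOL)
        with np.errstate(divide="ignore"):
            w = d ** (-power)
        w[hit_i] = 0.0  # rows with a coincident point get that value exactly
        with np.errstate(invalid="ignore"):
            block = (w @ values) / w.sum(axis=1)
        if len(hit_i):
            first = pd.Series(hit_j, index=hit_i).groupby(level=0).first()
            block[first.index.to_numpy()] = values[first.to_numpy()]
        if max_radius is not None:
            mask[s:s + step] = d.min(axis=1) > max_radius
        est[s:s + step] = block
    return est, mask


def idw_interpolate(points: ObservationSet, spec: GridSpec, power: float = 2.0,
                    max_radius: float | None = None) -> GridField:
    """Inverse-distance-power interpolation of ``points`` onto ``spec``.

    All points contribute to every cell (global neighborhood) unless
    ``max_radius`` is set, in which case cells with no point inside the
    radius are masked.
    """
    if points.n == 0:
        raise EmptyInputError("no points to interpolate")
    if power <= 0:
        raise ValueError(f"power must be > 0, got {power}")
    uu, vv = np.meshgrid(spec.u_centers, spec.v_centers)
    targets = np.column_stack([uu.ravel(), vv.ravel()])
    est, mask = _idw_at(targets, points.coords, points.pm25, power, max_radius)
    values = est.reshape(spec.ny, spec.nx)
    return GridField(spec=spec, values=values,
                     mask=mask.reshape(spec.ny, spec.nx))


@dataclass
class MapEvaluation:
    rmse: float
    errors: pd.DataFrame   # station_id, observed, estimated, error
    n_excluded: int        # stations outside the valid mapped area


def evaluate_map(field: GridField | None, stations: ObservationSet,
                 mode: str = "grid_lookup", points: ObservationSet | None = None,
                 power: float = 2.0) -> MapEvaluation:
    """Score a concentration map against reference-station readings.

    ``grid_lookup`` bilinearly samples ``field`` at each station
    coordinate; stations in masked or out-of-grid areas are excluded with
    a warning.  ``loo_idw`` ignores the grid and re-runs IDW at each
    station location directly from ``points`` (the calibrated sensors).
    """
    if stations.n == 0:
        raise EmptyInputError("no stations to evaluate against")
    if mode == "grid_lookup":
        if field is None:
            raise ValueError("grid_lookup mode requires a GridField")
        vals = np.where(field.mask, np.nan, field.values)
        interp = RegularGridInterpolator(
            (field.spec.v_centers, field.spec.u_centers), vals,
            method="linear", bounds_error=False, fill_value=np.nan)
        est = interp(stations.coords[:, ::-1])
    elif mode == "loo_idw":
        if points is None:
            raise ValueError("loo_idw mode requires the calibrated point set")
        est, _ = _idw_at(stations.coords, points.coords, points.pm25, power, None)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    ok = np.isfinite(est)
    n_excluded = int((~ok).sum())
    if n_excluded:
        warnings.warn(f"{n_excluded} station(s) outside the mapped area excluded",
                      stacklevel=2)
    if ok.sum() == 0:
        raise EmptyInputError("no station falls inside the mapped area")
    err = stations.pm25[ok] - est[ok]
    frame = pd.DataFrame({
        "station_id": stations.frame.loc[ok, "id"].to_numpy(),
        "observed": stations.pm25[ok],
        "estimated": est[ok],
        "error": err,
    })
    return MapEvaluation(rmse=float(np.sqrt(np.mean(err ** 2))), errors=frame,
                         n_excluded=n_excluded)
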