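"""Global and spatially varying-coefficient calibration models.

The calibration problem: regulatory (reference-grade) PM2.5 readings Y are
regressed on collocated low-cost readings x (optionally plus further
covariates such as relative humidity).  Two models are provided:

* **Global (nonspatial)** — ordinary least squares, a single coefficient
  vector (β₀, β₁, …, β_B) applied to every sensor.

* **Spatial** — a kernel-based varying-coefficient model (geographically
  weighted regression): at any location (u, v) the coefficients solve a
  weighted least-squares problem

      β̂(u, v) = [Xᵀ W(u, v) X]⁻¹ Xᵀ W(u, v) Y,

  with Gaussian distance-decay weights W_jj = exp(−d_j²/b²), where d_j is
  the planar distance (meters) from (u, v) to training pair j's anchor and
  b is the bandwidth.  The bandwidth is selected by leave-one-out
  cross-validation over a candidate grid.

Calibration of a sensor network replaces each sensor's PM2.5 with
β₀ + Σ β_b x_b; for the spatial model the coefficients are re-solved at
each sensor's own coordinate (true varying-coefficient prediction, not
interpolation of stored anchor coefficients).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .collocation import CollocatedPairs
from .errors import (
    BandwidthSelectionError,
    ConfigurationError,
    EmptyInputError,
    SingularFitError,
    UnderdeterminedFitError,
)
from .io import ObservationSet

logger = logging.getLogger(__name__)

#: kernel weights below this are treated as exactly zero
WEIGHT_FLOOR = 1e-12
#: condition-number threshold beyond which the local normal matrix is ridged
COND_THRESHOLD = 1e10
#: default ridge scale (multiplied by trace(A)/p)
DEFAULT_RIDGE_EPSILON = 1e-8


def gaussian_weight(d, b):
    """Gaussian distance-decay kernel w = exp(−d²/b²).

    ``d`` distance in meters (scalar or array, ≥ 0); ``b`` bandwidth in
    meters (> 0).  Equals 1 at d = 0 and decays strictly monotonically.
    """
    if b <= 0:
        raise ValueError(f"bandwidth must be > 0, got {b}")
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be >= 0")
    w = np.exp(-((d / b) ** 2))
    return float(w) if w.ndim == 0 else w


def _design(pairs: CollocatedPairs) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Design matrix with intercept, response, and anchors; rows with a
    missing covariate are dropped here (fit time), per the data contract."""
    X = np.column_stack([np.ones(pairs.n), pairs.X])
    y = pairs.y
    anchors = pairs.anchors
    ok = np.all(np.isfinite(X), axis=1) & np.isfinite(y)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.info("dropping %d pair(s) with missing covariates at fit time", n_bad)
    return X[ok], y[ok], anchors[ok]


@dataclass
class GlobalCalibration:
    """A single OLS coefficient vector for the whole network."""

    beta: np.ndarray  # (B+1,) — intercept first
    n_train: int
    covariate_names: tuple[str, ...] = ("pm25",)

    @property
    def B(self) -> int:
        return len(self.beta) - 1

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Calibrated values for an (n, B) covariate matrix."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return self.beta[0] + X @ self.beta[1:]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "model": "global",
                "beta": [float(b) for b in self.beta],
                "n_train": self.n_train,
                "covariates": list(self.covariate_names),
            }, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "GlobalCalibration":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(np.asarray(doc["beta"], dtype=float), doc["n_train"],
                   tuple(doc["covariates"]))


@dataclass
class SpatialCalibration:
    """Varying-coefficient calibration: bandwidth + per-anchor coefficients.

    ``local_coefficients`` holds β̂(u_i, v_i) at every training anchor
    (row-aligned with ``training_pairs``); predictions elsewhere re-solve
    the weighted least squares at the requested coordinate using the
    retained training pairs.
    """

    bandwidth: float
    training_pairs: CollocatedPairs
    local_coefficients: np.ndarray  # (n, B+1)
    ridge_epsilon: float = DEFAULT_RIDGE_EPSILON
    covariate_names: tuple[str, ...] = ("pm25",)

    def __post_init__(self) -> None:
        if self.bandwidth <= 0:
            raise ValueError("bandwidth must be > 0")
        if len(self.local_coefficients) != self.training_pairs.n:
            raise ValueError("one coefficient vector per training pair required")
        if not np.all(np.isfinite(self.local_coefficients)):
            raise ValueError("non-finite local coefficients")

    @property
    def B(self) -> int:
        return self.local_coefficients.shape[1] - 1

    def coefficients_at(self, targets: np.ndarray) -> np.ndarray:
        """β̂ solved afresh at each (u, v) row of ``targets``."""
        return _batch_local(np.atleast_2d(targets), self.training_pairs,
                            self.bandwidth, self.ridge_epsilon)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "model": "spatial",
                "bandwidth_m": float(self.bandwidth),
                "ridge_epsilon": float(self.ridge_epsilon),
                "covariates": list(self.covariate_names),
                "local_coefficients": self.local_coefficients.tolist(),
                "training_pairs": self.training_pairs.frame.to_dict(orient="list"),
                "max_distance_m": (None if math.isinf(self.training_pairs.max_distance)
                                   else float(self.training_pairs.max_distance)),
                "n_excluded": int(self.training_pairs.n_excluded),
            }, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SpatialCalibration":
        with open(path) as fh:
            doc = json.load(fh)
        pairs = CollocatedPairs(
            pd.DataFrame(doc["training_pairs"]),
            covariate_names=tuple(doc["covariates"]),
            max_distance=(math.inf if doc.get("max_distance_m") is None
                          else doc["max_distance_m"]),
            n_excluded=doc.get("n_excluded", 0),
        )
        return cls(doc["bandwidth_m"], pairs,
                   np.asarray(doc["local_coefficients"], dtype=float),
                   doc.get("ridge_epsilon", DEFAULT_RIDGE_EPSILON),
                   tuple(doc["covariates"]))


def fit_global(pairs: CollocatedPairs) -> GlobalCalibration:
    """Ordinary least-squares calibration over all retained pairs."""
    X, y, _ = _design(pairs)
    p = X.shape[1]
    if len(y) < p + 1:
        raise UnderdeterminedFitError(
            f"need at least {p + 1} pairs for a {p}-coefficient fit, have {len(y)}"
        )
    if np.linalg.matrix_rank(X) < p:
        raise SingularFitError("design matrix is rank deficient (constant covariate?)")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return GlobalCalibration(beta=beta, n_train=len(y),
                             covariate_names=pairs.covariate_names)


def _batch_local(targets: np.ndarray, pairs: CollocatedPairs, b: float,
                 ridge_epsilon: float) -> np.ndarray:
    """Solve the weighted normal equations at every target coordinate.

    The WLS solution is invariant under scaling of the weight vector, so
    the kernel is evaluated relative to each target's nearest anchor
    (exponent-shifted), which avoids underflow when the bandwidth is small
    compared to the target's isolation.  Relative weights below the floor
    are treated as zero, bounding the effective neighborhood; a target
    with fewer effective neighbors than coefficients is underdetermined.
    Near-singular normal matrices (condition number > 1e10) get
    ridge_epsilon · (tr A / p) added to the diagonal, and the event is
    logged.
    """
    if b <= 0:
        raise ValueError(f"bandwidth must be > 0, got {b}")
    X, y, anchors = _design(pairs)
    n, p = X.shape
    if n == 0:
        raise EmptyInputError("no usable training pairs")
    d2 = ((targets[:, 0, None] - anchors[None, :, 0]) ** 2
          + (targets[:, 1, None] - anchors[None, :, 1]) ** 2)
    expo = -d2 / (b * b)
    shift = expo.max(axis=1, keepdims=True)
    if not np.all(np.isfinite(shift)):
        raise UnderdeterminedFitError(
            "target too far from every training anchor for this bandwidth")
    W = np.exp(expo - shift)
    W[W < WEIGHT_FLOOR] = 0.0
    n_eff = (W > 0).sum(axis=1)
    if np.any(n_eff < p):
        bad = int((n_eff < p).sum())
        raise UnderdeterminedFitError(
            f"{bad} target location(s) have fewer than {p} training pairs with "
            f"non-negligible kernel weight at bandwidth {b:.0f} m"
        )
    A = np.einsum("tn,np,nq->tpq", W, X, X)
    rhs = np.einsum("tn,np,n->tp", W, X, y)
    cond = np.linalg.cond(A)
    ill = ~np.isfinite(cond) | (cond > COND_THRESHOLD)
    if np.any(ill):
        scale = np.trace(A[ill], axis1=1, axis2=2) / p
        A[ill] += (ridge_epsilon * scale)[:, None, None] * np.eye(p)
        logger.info("ridged %d near-singular local fit(s) (eps=%g)",
                    int(ill.sum()), ridge_epsilon)
    try:
        beta = np.linalg.solve(A, rhs[..., None])[..., 0]
    except np.linalg.LinAlgError as exc:  # exactly singular even after ridge
        raise SingularFitError(f"singular local normal matrix: {exc}") from exc
    if not np.all(np.isfinite(beta)):
        raise SingularFitError("non-finite local coefficients")
    return beta


def fit_local(target, pairs: CollocatedPairs, b: float,
              ridge_epsilon: float = DEFAULT_RIDGE_EPSILON) -> np.ndarray:
    """Weighted least-squares coefficient vector at one (u, v) target."""
    target = np.asarray(target, dtype=float).reshape(1, 2)
    return _batch_local(target, pairs, b, ridge_epsilon)[0]


def drop_incomplete(pairs: CollocatedPairs) -> CollocatedPairs:
    """Pairs with every model covariate present (fit-time filtering)."""
    ok = np.all(np.isfinite(np.column_stack([pairs.X, pairs.y])), axis=1)
    if ok.all():
        return pairs
    return CollocatedPairs(pairs.frame[ok].reset_index(drop=True),
                           pairs.covariate_names, pairs.max_distance,
                           pairs.n_excluded)


def fit_spatial(pairs: CollocatedPairs, b: float,
                ridge_epsilon: float = DEFAULT_RIDGE_EPSILON) -> SpatialCalibration:
    """Fit the varying-coefficient model: one local WLS per training anchor."""
    pairs = drop_incomplete(pairs)
    coeffs = _batch_local(pairs.anchors, pairs, b, ridge_epsilon)
    return SpatialCalibration(bandwidth=b, training_pairs=pairs,
                              local_coefficients=coeffs,
                              ridge_epsilon=ridge_epsilon,
                              covariate_names=pairs.covariate_names)


def _drop_pair(pairs: CollocatedPairs, i: int) -> CollocatedPairs:
    frame = pairs.frame.drop(index=pairs.frame.index[i]).reset_index(drop=True)
    return CollocatedPairs(frame, pairs.covariate_names, pairs.max_distance,
                           pairs.n_excluded)


def loo_rmse_spatial(pairs: CollocatedPairs, b: float,
                     ridge_epsilon: float = DEFAULT_RIDGE_EPSILON) -> float:
    """Leave-one-out CV RMSE of the spatial model at bandwidth ``b``:
    each held-out station is predicted by a local fit at its own anchor
    from the remaining n − 1 pairs."""
    pairs = drop_incomplete(pairs)
    X = np.column_stack([np.ones(pairs.n), pairs.X])
    y = pairs.y
    anchors = pairs.anchors
    errs = np.empty(pairs.n)
    for i in range(pairs.n):
        beta = fit_local(anchors[i], _drop_pair(pairs, i), b, ridge_epsilon)
        errs[i] = y[i] - X[i] @ beta
    return float(np.sqrt(np.mean(errs ** 2)))


def loo_rmse_global(pairs: CollocatedPairs) -> float:
    """Leave-one-out CV RMSE of the global OLS model."""
    pairs = drop_incomplete(pairs)
    X = np.column_stack([np.ones(pairs.n), pairs.X])
    y = pairs.y
    errs = np.empty(pairs.n)
    for i in range(pairs.n):
        mask = np.arange(pairs.n) != i
        beta, *_ = np.linalg.lstsq(X[mask], y[mask], rcond=None)
        errs[i] = y[i] - X[i] @ beta
    return float(np.sqrt(np.mean(errs ** 2)))


def default_bandwidth_candidates(pairs: CollocatedPairs, k: int = 8) -> list[float]:
    """k log-spaced bandwidths from the 5th percentile of anchor–anchor
    distances up to the network diameter."""
    a = pairs.anchors
    d = np.hypot(a[:, 0, None] - a[None, :, 0], a[:, 1, None] - a[None, :, 1])
    off = d[np.triu_indices(len(a), k=1)]
    lo = max(float(np.percentile(off, 5)), 1.0)
    hi = max(float(off.max()), lo * 2)
    return list(np.geomspace(lo, hi, k))


def select_bandwidth(pairs: CollocatedPairs,
                     candidates: list[float] | None = None,
                     ridge_epsilon: float = DEFAULT_RIDGE_EPSILON) -> float:
    """Choose the bandwidth minimising leave-one-out CV RMSE.

    Ties (within 1e-9 relative) break toward the larger bandwidth, i.e. the
    smoother, less local model.  Candidates whose local fits are degenerate
    everywhere are skipped; if none survives, selection fails.
    """
    if candidates is None:
        candidates = default_bandwidth_candidates(pairs)
    if not candidates:
        raise BandwidthSelectionError("empty candidate list")
    if any(c <= 0 for c in candidates):
        raise ValueError("bandwidth candidates must be > 0")
    if pairs.n < pairs.B + 3:
        raise UnderdeterminedFitError(
            f"need at least B + 3 = {pairs.B + 3} pairs for cross-validation"
        )
    scores: list[tuple[float, float]] = []
    for b in sorted(candidates):
        try:
            scores.append((float(b), loo_rmse_spatial(pairs, b, ridge_epsilon)))
        except (UnderdeterminedFitError, SingularFitError) as exc:
            logger.info("bandwidth %.0f m skipped: %s", b, exc)
    if not scores:
        raise BandwidthSelectionError("every candidate bandwidth was degenerate")
    best_rmse = min(s for _, s in scores)
    # largest bandwidth within a relative hair of the minimum
    best = max(b for b, s in scores if s <= best_rmse * (1 + 1e-9))
    logger.info("selected bandwidth %.0f m (LOO RMSE %.3f)", best, best_rmse)
    return best


def calibrate(model, sensors: ObservationSet) -> ObservationSet:
    """Apply a calibration model to a sensor network.

    Returns a copy of ``sensors`` whose pm25 is the calibrated value
    β₀ + Σ β_b x_b; for the spatial model the coefficients are solved at
    each sensor's own coordinate.  Negative predictions are floored at
    0 µg/m³ (counted and logged).
    """
    if sensors.n == 0:
        raise EmptyInputError("no sensors to calibrate")
    names = model.covariate_names
    cols = []
    for name in names:
        if name == "pm25":
            cols.append(sensors.pm25)
        elif name in sensors.frame.columns:
            cols.append(sensors.frame[name].to_numpy(dtype=float))
        else:
            raise ConfigurationError(
                f"model covariate {name!r} missing from sensor set"
            )
    X = np.column_stack(cols)
    if isinstance(model, GlobalCalibration):
        pred = model.predict(X)
    elif isinstance(model, SpatialCalibration):
        beta = model.coefficients_at(sensors.coords)
        pred = beta[:, 0] + np.einsum("nb,nb->n", X, beta[:, 1:])
    else:
        raise ConfigurationError(f"unknown model type {type(model).__name__}")
    n_floored = int((pred < 0).sum())
    if n_floored:
        logger.info("floored %d negative calibrated value(s) at 0", n_floored)
    return sensors.with_pm25(np.maximum(pred, 0.0))
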