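"""Model evaluation: residuals, R², RMSE, distribution summaries.

The residual at station i is e_i = Y_i − Y'_i, the reference reading minus
the calibrated low-cost value at the paired location.  R² is 1 − SS_res /
SS_tot with SS_tot taken about the mean of Y; RMSE is sqrt(mean e²).
Normal-probability pairs (ordered residuals vs theoretical normal
quantiles) are provided for visual normality checks rather than formal
tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .collocation import CollocatedPairs
from .errors import AlignmentError, EmptyInputError, UndefinedCorrelationError
from .io import ObservationSet

HIST_BIN_WIDTH = 10.0  # µg/m³, matching regulatory-report histogram granularity


@dataclass
class ResidualReport:
    residuals: np.ndarray        # µg/m³, one per station pair
    rmse: float                  # µg/m³
    r_squared: float             # in (−∞, 1]
    n: int
    normality: tuple[np.ndarray, np.ndarray]  # (ordered residuals, normal quantiles)

    def to_frame(self) -> pd.DataFrame:
        ordered, quantiles = self.normality
        return pd.DataFrame({
            "ordered_residual": ordered,
            "normal_quantile": quantiles,
        })

    def summary(self) -> str:
        return (f"n={self.n}  RMSE={self.rmse:.3f} ug/m3  R2={self.r_squared:.4f}  "
                f"residual range [{self.residuals.min():.2f}, {self.residuals.max():.2f}]")


def residual_report(pairs: CollocatedPairs, calibrated_y) -> ResidualReport:
    """Residual diagnostics for per-pair calibrated predictions.

    ``calibrated_y`` must align one-to-one with ``pairs`` (same order).
    Normal-probability quantiles are Φ⁻¹((i − 0.5)/n) against the sorted
    residuals.
    """
    calibrated_y = np.asarray(calibrated_y, dtype=float)
    if calibrated_y.shape != (pairs.n,):
        raise AlignmentError(
            f"calibrated values ({calibrated_y.shape}) do not align with "
            f"{pairs.n} pairs"
        )
    y = pairs.y
    e = y - calibrated_y
    n = len(e)
    rmse = float(np.sqrt(np.mean(e ** 2)))
    ss_res = float(np.sum(e ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    ordered = np.sort(e)
    quantiles = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    return ResidualReport(residuals=e, rmse=rmse, r_squared=r2, n=n,
                          normality=(ordered, quantiles))


@dataclass
class DistributionSummary:
    mean: float          # µg/m³
    sd: float            # µg/m³, population denominator n
    variance: float      # (µg/m³)²
    bin_edges: np.ndarray   # 0, 10, 20, … covering the data
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "bin_left": self.bin_edges[:-1],
            "bin_right": self.bin_edges[1:],
            "count": self.counts,
        })


def distribution_summary(obs: ObservationSet) -> DistributionSummary:
    """Mean, population SD/variance and a fixed-width 10 µg/m³ histogram."""
    if obs.n == 0:
        raise EmptyInputError("empty observation set")
    x = obs.pm25
    mean = float(x.mean())
    var = float(x.var())  # population (ddof=0)
    top = max(HIST_BIN_WIDTH, np.ceil(x.max() / HIST_BIN_WIDTH) * HIST_BIN_WIDTH)
    edges = np.arange(0.0, top + HIST_BIN_WIDTH, HIST_BIN_WIDTH)
    counts, _ = np.histogram(x, bins=edges)
    return DistributionSummary(mean=mean, sd=float(np.sqrt(var)), variance=var,
                               bin_edges=edges, counts=counts)


def pearson_correlation(a, b) -> float:
    """Pearson r between two equal-length series (n ≥ 3, nonzero variance)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise AlignmentError("series lengths differ")
    if len(a) < 3:
        raise EmptyInputError("need at least 3 points for a correlation")
    if a.var() == 0 or b.var() == 0:
        raise UndefinedCorrelationError("zero variance in one of the series")
    return float(stats.pearsonr(a, b).statistic)
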