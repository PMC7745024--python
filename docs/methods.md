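# Methods

This note records the statistical model implemented by `pmcal`, the
choices made where the design was genuinely open, and what the synthetic
benchmark does and does not demonstrate.

## Calibration model

The calibration set consists of n collocated records: the reference
reading Y_i at regulatory station i, the covariate vector
X_i = (x_1i, …, x_Bi) from the nearest low-cost sensor (x_1 is the
sensor's PM2.5; further covariates such as relative humidity are
optional, default B = 1), and the station coordinate (u_i, v_i) in
planar meters.

The **global model** is OLS on E(Y|X) = β₀ + Σ β_b x_b, solved by QR
(`numpy.linalg.lstsq`) after an explicit rank check — a rank-deficient
design (e.g. a constant covariate) is an error, not a silent pseudo-
inverse.

The **spatial model** lets every coefficient be a function of location,
estimated at any target (u, v) by weighted least squares with Gaussian
distance-decay weights w_j = exp(−d_j²/b²). This is the standard
geographically weighted regression estimator; the kernel is isotropic
and the bandwidth b (meters) is fixed, not adaptive. Coefficients are
stored at the n training anchors for diagnostics, but **prediction at a
sensor re-solves the weighted problem at the sensor's own coordinate**
rather than interpolating stored coefficients — consistent with the
estimator's definition at any location, at negligible cost (the batch
solver builds all n_sensor 2×2 normal systems in one einsum).

### Numerical treatment of the local solve

The WLS solution is invariant under scaling of the weight vector. The
solver therefore evaluates the kernel *relative to the target's nearest
anchor* (shifting the exponent by max_j(−d_j²/b²)), which keeps the
nearest anchor's weight at exactly 1 and avoids underflow when b is
small relative to the target's isolation. Relative weights below 10⁻¹²
are zeroed to bound the effective neighborhood; a target with fewer
effective neighbors than coefficients raises an underdetermined-fit
error. Normal matrices with condition number above 10¹⁰ receive a ridge
of `ridge_epsilon` (default 10⁻⁸) × tr(A)/p on the diagonal, and the
event is logged — this covers locally constant covariates without
changing well-posed fits at reported precision.

### Bandwidth selection

`select_bandwidth` minimizes leave-one-out cross-validated RMSE: each
held-out station is predicted by a local fit at its own anchor from the
remaining n − 1 pairs. The default candidate grid is 8 log-spaced values
from the 5th percentile of anchor–anchor distances to the network
diameter; ties break toward the larger (smoother) bandwidth. Candidates
for which some fold is underdetermined are skipped; if all are, the
selection fails loudly. LOO was chosen over k-fold because n is small
(~70) and the estimator is cheap at that scale.

## Collocation

Matching is station-centric — one pair per regulatory station, using the
single nearest sensor — because the regression index runs over the n
reference observations; sensor-centric matching would over-weight dense
sensor clusters. Distance ties break toward the lexicographically
smallest sensor id, making the pairing total and deterministic. The
anchor coordinate of a pair is the *station's* coordinate; within the
2 km separation cap the choice is numerically minor, but it is a choice.
Pairs beyond 2 km (configurable) are excluded; the filter is idempotent
and its running exclusion count is reported.

## Coordinates

Input may be geographic (lon/lat degrees) or pre-projected meters. The
built-in projection is a local equirectangular about a reference
latitude: u = R·cos(ref_lat)·Δλ, v = R·Δφ, R = 6 371 000 m. Over a few
hundred km at low latitude its distance distortion is below 1% (tested
against the great-circle formula), which is well inside the kernel's
insensitivity; users needing a formal CRS can pass projected u/v
columns directly.

## Diagnostics

Residuals e_i = Y_i − Y′_i; RMSE = √(mean e²); R² = 1 − SS_res/SS_tot
about the mean of Y. Distribution summaries use the population (n)
denominator for SD/variance, and histograms use fixed 10 µg/m³ bins.
For the spatial model both the in-sample statistics at the anchors and
the LOO-CV RMSE are reported, explicitly labeled — in-sample figures for
a local smoother are optimistic, and the LOO number is the honest
generalization estimate. Normal-probability pairs use quantiles at
(i − 0.5)/n for visual normality checks; no formal test is run.

## Mapping

IDW with power 2 (configurable) on a regular grid (default 2 km cells;
grid covers the point bounding box with a ceil-plus-one cell-count
convention). All points contribute to every cell by default; an optional
`max_radius` masks cells with no point nearby (oceans, out-of-network
areas). A cell center within 10⁻⁹ m of a data point takes that point's
value exactly, preventing division by zero and making the interpolant
honor the data. Estimates are convex combinations, hence bounded by the
observed min/max. Negative calibrated concentrations are floored at
0 µg/m³ before mapping, with a logged count. Map accuracy is reported
two ways — bilinear grid lookup at station coordinates, and direct IDW
re-evaluation at the stations — since which of the two a published
mapping RMSE refers to is often unstated.

## Synthetic benchmark

The generator emulates one time slice of a dense biased network paired
with a sparse reference network. Ground truth is a closed form:
background + K Gaussian plumes. Sensors read
α(u,v) + γ(u,v)·truth + ε; stations read truth + ε_ref. The bias
surfaces are low-order linear/trigonometric forms with explicit
coefficients — not random fields — so the implied true calibration
surfaces (slope 1/γ, intercept −α/γ) are closed-form and recovery tests
are sharp.

The default snapshot: 150 km × 400 km coastal domain, 2 963 sensors and
76 stations placed with a westward density bias, three plumes (central-
west and southwest hotspots, weaker north) over a 12 µg/m³ background,
γ ∈ [1.1, 1.8], α ∈ [0, 15] µg/m³, sensor noise SD 5 µg/m³, reference
noise SD 1.5 µg/m³, and a humid (~82%) relative-humidity surface. The
plume constants were set so that the station network's sample moments
land near a polluted-day regulatory snapshot (mean ≈ 37, SD ≈ 17.5
µg/m³) and sensors read systematically high. Each station is guaranteed
a sensor within 80–700 m, so collocation always succeeds; the
"exclusion" variant additionally isolates the 7 most mutually distant
stations so their nearest sensor lies 2.1–3.4 km away, exercising the
2 km filter deterministically.

Two controlled variants support the estimator tests. The
**linear-slope** benchmark is noise-free with γ linear in easting and a
densified anchor set (150 stations, 20–150 m collocation offsets); its γ
span (0.15 over 150 km) is deliberately gentle so the coefficient
length-scale is far above both the anchor spacing and the CV-selected
bandwidth — the regime where the local estimator should track the true
surface. With steep gradients the measured error is dominated by
kernel-scale smoothing bias, which is a property of any kernel smoother,
not an implementation defect. The **homogeneous** variant (constant γ,
α) is the no-overfit control: the spatial model must match, not beat,
the global one there.

What passing these tests does *not* show about real networks: the
synthetic bias surfaces are smooth and noiseless in form, whereas real
sensor bias has sensor-level idiosyncrasies (age, siting, firmware),
humidity responses that are nonlinear and temporally varying, and truth
fields with sharp local sources. The benchmark validates the estimator
and pipeline mechanics, not the field accuracy of any particular
deployment.

## Problem sizes and determinism

The shipped tests and the acceptance script run the full-size default
network (2 963 sensors, 76 stations) with 2 km grids; multi-seed
comparisons use 10 seeds. All randomness flows from a single
`numpy.random.default_rng(seed)` per scenario, so identical config +
seed reproduce byte-identical CSV/JSON/ASC outputs (floats are written
with 17 significant digits and re-read with round-trip parsing).

## Known limitations

- One time slice per invocation; no temporal pooling, resampling or
  drift modeling.
- Fixed isotropic Gaussian kernel; no adaptive (k-nearest) bandwidth,
  no anisotropy, no elevation term.
- IDW only for mapping; kriging would provide uncertainty but is out of
  scope.
- The average reported "mean pair distance" is over retained pairs
  (stations), which may differ from a sensor-centric average in dense
  clusters.
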