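# Methods

Assumptions, parameter defaults, generator design and numerical choices for
`streammetab`. Units follow the package convention: velocities m s⁻¹, O2
µmol L⁻¹ (≡ mmol m⁻³), fluxes mmol O2 m⁻² h⁻¹ (hourly) or mmol O2 m⁻² d⁻¹
(daily), PAR µmol quanta m⁻² s⁻¹ (instantaneous) or mol quanta m⁻² d⁻¹
(daily total). Positive flux = O2 released by the bed; positive NEM = net
autotrophy.

## 1. Aquatic eddy covariance (`streammetab.aec`)

### Model

The benthic O2 exchange is the turbulent vertical flux at the measurement
point, `F_EC = mean(w'C') · 3600`, under the assumptions of (i) a
well-mixed, horizontally homogeneous water column below the sensor,
(ii) stationarity within each averaging window, and (iii) negligible mean
vertical advection after tilt correction. Under (i) the O2 stored between
bed and sensor changes as `F_storage = (dC/dt) · h`, and the true
sediment–water exchange is `F_benthic = F_EC + F_storage`.

### Processing order

Fixed and logged in the diagnostics:
`quality_filter → block_average → despike → double_rotation → detrend →
time_shift → flux`. Rotation is computed from despiked velocities;
detrending (Reynolds decomposition) must precede the covariance; the lag
search must operate on detrended fluctuations so slow trends cannot anchor
spurious lags.

### Steps and defaults

* **Quality filter** — samples with beam correlation < 50 % or SNR < 10 dB
  are replaced by linear interpolation; a record with more than
  `max_gap_fraction = 0.05` failing samples is rejected rather than
  patched. The 50/10 thresholds are conventional acoustic-velocimeter
  screening values; the 5 % ceiling keeps interpolation a repair, not a
  model.
* **Block averaging** — records faster than the 8 Hz target rate are
  averaged in non-overlapping blocks. Averaging is linear, so it preserves
  covariances of the resolved scales (verified: 64 Hz → 8 Hz changes a
  synthetic flux by < 5 %).
* **Despiking** — modified 3-D phase-space method: each channel is mapped
  into (f, Δf, Δ²f) space; points outside the ellipsoid defined by the
  universal threshold λ = √(2 ln n) times a robust (MAD-based) standard
  deviation on each axis, including the rotated (f, Δ²f) ellipse, are
  spikes, replaced by linear interpolation and re-checked iteratively
  (≤ 10 passes). The MAD estimator keeps the threshold itself insensitive
  to the spikes being detected. False-positive rate on clean Gaussian and
  AR(1) series is ~10⁻⁵ per sample (tested). Derivative coordinates flag a
  few neighbours of each true spike; since replacement is interpolation,
  this costs only a small loss of variance at isolated points.
* **Double rotation** — yaw then pitch rotation so mean v = w = 0. Both are
  proper rotations, so per-sample speed is preserved to machine precision
  (an exactness test, ≤ 1e-12 relative).
* **Detrending** — per-window linear detrend with
  `detrend_window = 300 s`. The window must be long against the integral
  timescale of the turbulence (~1 s here) so the covariance is resolved,
  and short against diel/storage trends so they are removed from the
  fluctuations; 5 min is the conventional compromise and
  `detrend_window_sweep` exposes the sensitivity. A linear trend inside the
  window absorbs slow sinusoids with period ≳ window length; signals with
  periods well below the window pass through intact (tested at 2.5 s).
* **Time-shift correction** — the O2 sensor responds later than the
  velocimeter; per window, the non-negative integer-sample lag (≤
  `max_lag = 2 s`) maximizing |cov(w', C'(t−τ))| is applied, with the
  per-hour lag taken as the median across windows to avoid lag-fishing on
  noise (a white-noise test verifies no induced bias). Only physical
  (positive) lags are searched.
* **Flux and error** — hourly flux is the mean of per-window covariances;
  its standard error is the window-to-window scatter divided by √n_windows,
  which is robust to within-window autocorrelation.
* **Velocity-derived diagnostics** — friction velocity
  `u* = √max(0, −mean(u'w'))` (flagged when floored); roughness length from
  the law of the wall `z0 = h·exp(−κU/u*)`, κ = 0.41; drag coefficient
  `C_D = (u*/U)²`.
* **Footprint** — the cumulative footprint is parameterized as
  `F(x) = exp(−x_c/x)` with `x_c = h·ln(h/z0)/κ²`, giving a 90 % fetch
  `L90 = x_c / (−ln 0.9)` and a lateral width of 6 h. This is an own
  analytical law-of-the-wall parameterization (the shape of a
  one-dimensional advection–diffusion footprint with the length scale set
  by the log-law travel time); for measurement heights 0.10–0.19 m and z0
  0.4–1.2 mm it yields lengths of ~25–66 m and widths of 0.6–1.1 m,
  inside the envelope expected for such deployments (22–181 m × 0.5–1.5 m).
  It is a diagnostic, not an input to the flux.

## 2. Synthetic generators (`streammetab.synthetic`)

### Turbulence

Velocity and O2 fluctuations are unit-variance AR(1) processes (integral
timescale 1 s at 8 Hz) built from shared Gaussian innovations so that
`cov(u', w') = −u*²` and `cov(w', C')` equals the requested flux exactly in
expectation. Scales: σ_w = 1.2 u*, σ_u = 2.5 u* (log-layer anisotropy
ratios), σ_c chosen to give a w′–C′ correlation of 0.4 with a floor of
0.15 mmol m⁻³. On top of the correlated field the generator adds, in
order: mean flow and sensor tilt, a linear storage trend on O2, a sensor
lag on O2, instrument noise, spikes (default rate 10⁻³ per sample), and QC
failures (default 0.5 %).

**Noise defaults are set a priori from an error budget, not tuned to the
tests.** With a 1 s integral timescale, a 3-h record contains ≈ 5400
effective samples, so the covariance sampling error alone is ~4–6 % of a
mid-range flux. Instrument noise of 0.003 m s⁻¹ (velocity) and
0.10 µmol L⁻¹ (O2) is uncorrelated between channels and therefore adds
variance but no bias; it inflates the sampling error only marginally at
these levels. This places end-to-end recovery safely inside the 10 %
acceptance band *by design* — measured recovery error across truths
±2…±10 mmol m⁻² h⁻¹ and several seeds is 3–7 %.

Realism limits: the AR(1) spectrum lacks an inertial subrange slope; waves,
coherent structures and O2-optode thermal transients are not modelled;
spikes are single-sample, not bursts.

### Bottles, diel fluxes, hydrographs, driver ensembles

* Bottle sets integrate a constant day rate (clear) and night rate (dark,
  plus the day-period dark rate) under a half-sinusoid PAR curve with
  night PAR < 2 µmol quanta m⁻² s⁻¹, with Gaussian reading noise.
* `gen_diel_flux` draws hourly benthic flux from a tanh P–E truth plus
  noise.
* Hydrographs are a slow exponential base-flow recession plus storm pulses
  with a one-day linear rise and fast exponential recession; the base-flow
  component is stored as ground truth, so the separated BFR can be compared
  against an exact value.
* Driver ensembles impose `NEM = a·PAR + b·BFR(window) + c + noise` across
  synthetic sites, exposing the generating coefficients and window.

## 3. Bottles and water-column metabolism (`streammetab.bottles`)

Day/night partition at PAR ≥ 2 µmol quanta m⁻² s⁻¹ (optode/PAR-sensor dark
threshold). Rates are OLS slopes over ≥ 5 samples; the daytime rate
averages clear-bottle daytime slopes across depth positions; the nighttime
(respiration) rate averages dark-bottle day- and night-period slopes with
equal weight. Fits with R² < 0.8 are flagged, constant series are
degenerate (rate 0, R² = NaN). Areal scaling: `ER_w = |night|·24·depth`,
`GPP_w = (day − night)·daylight·depth` floored at 0,
`NEM_w = (day·daylight + night·night_h)·depth`; an undetectable day rate
falls back to the night rate scaled to 24 h. Areal GPP below
0.1 mmol m⁻² d⁻¹ is reported "<0.1".

## 4. Budgets (`streammetab.budget`, `streammetab.campaigns`)

Definitions as in the README. GPP is floored at zero (a day flux more
negative than the night flux is measurement noise around zero production).
Compartments combine by elementwise addition; annual means are unweighted
means of exactly four seasons, with missing seasons only ever filled
through an explicit, flagged substitution map. `weighted_period_mean`
implements time-weighting of a short production peak over a season
((1·253.2 + 11·(−7.5))/12 = 14.2 for the bundled clay-reach spring bloom).

The bundled dataset stores the published campaign summaries verbatim. Known
internal artifacts of that table, handled explicitly rather than silently:

* one daylight/night split sums to 24.1 h (printed-precision artifact);
  night hours are re-derived as 24 − daylight;
* the clay-reach winter water column is missing (flooding) and is
  substituted from autumn, flagged;
* two seasons report GPP_b = 0 although the printed day/night means differ
  (GPP there follows the flat light-response fit, not the raw means), and
  one row's GPP/NEM pair is not reconstructable from its own printed hourly
  fluxes within rounding; the tests exclude exactly these cells and assert
  reconstruction for all others.

## 5. Light response (`streammetab.light`)

Saturating model `P = Pmax·tanh(E/Ek) − R` fitted by nonlinear least
squares with initial values from the data (Pmax₀ = range of P, Ek₀ = median
daytime E, R₀ = −mean nighttime P) and positivity bounds on Pmax and Ek.
Model selection: the tanh model is accepted only if the fitted Ek lies
inside the sampled light range (Ek < 0.8·max E — saturation actually
observed) *and* it reduces the residual sum of squares by > 5 % relative to
the linear fit; otherwise the linear model `P = αE − R` is used; if the
95 % confidence interval of α spans zero the response is flat
(respiration-only), as in seasons without a light response. Both thresholds
are conservative screening constants fixed before testing. Compensation
irradiance `Ec = Ek·atanh(R/Pmax)` is defined only for 0 < R < Pmax.

## 6. Hydrology and drivers (`streammetab.hydrology`)

* **Discharge** — midsection velocity–area method; exact for piecewise
  constant/linear profiles on the station grid and additive over lateral
  segments.
* **Base-flow separation** — UK smoothed-minima procedure with 5-day
  blocks and a 0.9 turning-point factor (the standard constants of that
  method, exposed as configuration). Block minima scaled by 0.9 that do not
  exceed both neighbours are turning points; base flow is their linear
  interpolation, anchored at the first/last block minima and capped at the
  observed discharge, so 0 ≤ BFR ≤ 1 always.
* **BFR** — mean of daily base-flow/discharge ratios over a trailing
  window ending on the campaign's last day (default 9 days), i.e. the flow
  regime *leading into and including* the campaign.
* **Driver regressions** — OLS via statsmodels. The combined model is
  additive linear, `NEM = a·PAR + b·BFR + c`, a design decision (the
  functional form is an open question; no interaction term is claimed). By
  OLS nesting its R² is never below either single-driver fit.
  `window_scan` sweeps BFR windows of 2–30 days and reports the R² profile
  and its argmax.

## 7. Build-versus-buy

Standard numerics are delegated: OLS and p-values to
scipy.stats/statsmodels, nonlinear fitting to scipy.optimize, filtering to
scipy.signal. The domain primitives — despiking, rotation, detrending,
lag search, covariance flux, storage correction, footprint, smoothed-minima
separation, midsection discharge — are implemented here because they *are*
the subject of the package.

## 8. Limitations

* The storage correction assumes a well-mixed column; stratified or
  laterally heterogeneous reaches violate `F_storage = (dC/dt)·h`.
* No spectral corrections (sensor separation, path averaging, high-pass
  loss from detrending) are applied; for the default geometry these are
  second-order relative to the ~5 % sampling error.
* The footprint parameterization is analytical and unvalidated against
  tracer or LES studies; treat it as an order-of-magnitude siting
  diagnostic.
* Bottle incubations exclude reaeration and bed exchange by construction;
  the package does not model gas exchange with the atmosphere at all
  (fluxes are measured below the air–water interface).
* The synthetic generators verify the *estimators*, not the field
  conditions; passing the property suite does not certify performance on
  wave-contaminated or strongly nonstationary records.
* Annual budgets from four seasonal snapshots assume each campaign
  represents its season; no uncertainty is propagated into the annual mean.
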