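# Methods

## Model

The package models the monthly fraction of firearm-owning households in
`n` spatial units (states) as a first-order spatial Durbin panel process.
Month `m`'s ownership vector `Y_m` combines

* a contemporaneous spatial lag `ρ W_m Y_m` (ownership co-moves across
  nearby, populous states),
* a 12-month own lag `τ Y_{m−12}` and its spatial counterpart
  `η W_m Y_{m−12}` (annual memory),
* the previous month's proxies — background checks per capita `X⁽¹⁾`
  (units: checks/person/month) and fraction of suicides with firearms
  `X⁽²⁾` (dimensionless) — with coefficients split by survey response
  class (H/L), and their spatial lags `ψ⁽ʲ⁾ W X⁽ʲ⁾` unsplit,
* a linear yearly trend `γ d` (`d` = 0, 1, 2, … from the first modeled
  year; the origin is absorbed by the intercepts) and class intercepts
  `α⁽H⁾, α⁽L⁾`,
* iid Gaussian noise with variance `σ²`.

The response-class split exists because annual survey anchors from
sparsely sampled states are unreliable (a single respondent yields an
anchor of exactly 0 or 1); giving such states their own proxy
coefficients and intercept keeps them from distorting the rest of the
fit. A unit is H iff its respondent count strictly exceeds the threshold
(default 10) in **every** year; equality in any year gives L. The source
wording leaves the boundary case ambiguous; the strict reading is a
deliberate, configurable choice.

The model is linear and its output is not clipped to [0, 1]: clipping
would invalidate the Gaussian likelihood. A `clipped()` view exists for
display only.

### Weight matrix

`W_m[i, j] = p_j / (K_i D_ij)` with `K_i = Σ_{j≠i} p_j / D_ij`: the pull
of state j on state i grows with j's population and decays with the
great-circle (haversine, R = 6371 km) distance between centroids. Rows
sum to 1 exactly (checked at 1e-12); the diagonal is zero. Populations
are yearly, so there is one matrix per calendar year, applied to all 12
months. The metric used by the original analysis is unstated; haversine
is the natural choice for centroid coordinates, and the builder accepts a
precomputed distance matrix (or an arbitrary raw-weight function, row-
normalized on the way in) for alternatives. The all-zero null matrix
switches spatial interaction off entirely and reduces the model to an
ordinary linear regression; its row-sum invariant is waived.

One pairing subtlety: the spatial proxy term is written against the
weight matrix of the *proxy's* month (`W_{m−1} X_{m−1}`). Since `W` is
constant within a year this matters only at January boundaries, where
the previous year's matrix is used. The October-stacked estimation pairs
September proxies with the same year's matrix either way.

## Calibration

Survey anchors exist only for Octobers, so the estimation stacks the
`T−1` October cross-sections of years 2…T: the response block of year
`t` is its October survey vector; the regressors are the previous
October (the 12-month lag, taken from the survey), September's proxies
of year `t` split by H/L, their spatial lags, the trend dummy, and the
class indicators — `(T−1)·n` rows, 11 coefficient columns, and a
block-diagonal `W`. At the default study scale (n = 48, T = 20) this is
912 rows. A literal stack that included the burn-in year would regress
the first October on a copy of itself (the burn-in is initialized from
it); the stack therefore starts at the second survey year.

The Gaussian log-likelihood is

    ln L = −(N/2) ln(2πσ²) + ln|I − ρW| − e'e/(2σ²),
    e = Y − ρWY − Zδ,

with ρ restricted to the open interval `(1/min ω, 1/max ω)` given the
eigenvalues ω of the block W (real parts; for a row-stochastic matrix
the upper bound is 1). Two source typos are corrected deliberately: the
stacked equation is estimated with ρ multiplying WY (consistent with the
likelihood's residual), and the normalization constant is the standard
`2π` (not the literal `γ` the source prints inside the logarithm).

Estimation concentrates the likelihood: for candidate ρ, `δ̂(ρ) = δ₀ −
ρ δ_d` from two least-squares fits (Y on Z and WY on Z) and `σ̂²(ρ) =
e'e/N` in closed form, leaving a bounded scalar maximization over ρ
(Brent-style, on 99.9% of the spectral interval to avoid the boundary
singularities; tolerance 1e-8). The log-determinant is computed exactly
as `Σ ln|1 − ρω|` from the per-year block spectra — cheap at any
realistic n because the blocks are only n×n. A Barry–Pace Monte-Carlo
estimator is provided for large panels: the truncated series
`−Σ_k ρᵏ tr(Wᵏ)/k` with the first six moments computed exactly per block
(elementwise sums of W, W², W³ products) and higher powers estimated by
Gaussian Rayleigh quotients; with 100 draws and order 50 it tracks the
dense value to a fraction of a percent, because the stochastic part only
carries the ρ⁷ tail.

Standard errors come from the numerical Hessian of the full
log-likelihood at the optimum (pseudo-inverse, so degenerate directions
yield NaN rather than garbage); t-statistics are estimate/SE. The source
reports two slightly different t-value sets for the same fit, so no
attempt is made to reproduce a specific variance formula. Under the null
weight matrix ρ is unidentified (the likelihood is flat in it); it is
pinned at 0, the fit collapses to OLS of Y on Z, and ρ's SE is NaN.

## Prediction

Inference iterates the calibrated model monthly with σ² = 0 (the mean
path). The 12 months of a virtual burn-in year are filled with the first
survey year's October values. Each October's 12-month lag is replaced by
the *previous October's survey values* — the anchor that stops a
20-year recursion from drifting — while all other months use the model's
own output from 12 months earlier. A missing anchor falls back to the
model's value with a logged warning (the historical data had full
October coverage; synthetic data may not). Fit quality is summarized by
the October squared errors: SSE (sum) and MSE (SSE / number of compared
Octobers), nationally and per unit.

The national series is *not* an average of state outputs: national
proxies are built first (check counts reconstructed as rate ×
population and re-divided by total population; the suicide fraction
aggregated by counts when per-state suicide counts are supplied, else by
the population-weighted mean — an approximation, flagged as such) and
the model is iterated on them as a single unit. With one unit the
spatial terms vanish structurally, so the national series linearly
combines the aggregated proxies — which also means the spatial proxy
contributions (ψ terms) present in the state-level fit drop out, and a
national trajectory driven by spatially calibrated coefficients can sit
at a visibly different level than the state average. That is a property
of the procedure, not a bug; it is exactly the contrast the null-model
comparison (W = 0) is designed to expose.

## Causal pipeline

Series preparation follows the per-series plan: seasonal adjustment,
linear detrending, and symbolization. Seasonal adjustment is a classical
additive decomposition (centered 2×12 moving-average trend, month-mean
seasonal factors normalized to sum to zero — mean-preserving); the
ARIMA-model-based TRAMO/SEATS adjuster used in the original workflow is
deliberately not reimplemented, because the downstream analysis needs
only the seasonal component removed and the classical decomposition is
verifiable against closed forms (a pure period-12 sinusoid is
annihilated to machine precision). Detrending subtracts the OLS line on
the time index. An augmented Dickey-Fuller check (constant, AIC lag
selection, MacKinnon 5% critical values) guards stationarity; the
specification beyond the test's name is a documented default.

Symbolization: continuous series map to 1 where the next value is
strictly greater (ties → 0), shortening the series by one; event counts
map to 1 where at least one event occurred, preserving length. When a
triad mixes the two rules, all symbol series are truncated to the common
length (event series lose their final element) — the sources are silent
on this bookkeeping, so it is fixed here and logged.

Conditional transfer entropy uses a first-order embedding of binary
symbols: the plug-in joint distribution of `(X_{t+1}, X_t, Y_{t−lag},
Z_{t−lag})` over its 16 states, `TE = H(X_{t+1}|X_t,Z_t) −
H(X_{t+1}|X_t,Y_t,Z_t)` in bits (lag 0 is the main analysis; lags 1–11
probe delayed influence, with source and conditioner lagged together).
No small-sample bias correction is applied — the permutation null
absorbs estimator bias, matching the frequency-based description of the
original procedure.

Significance uses a local permutation scheme: source symbols are
shuffled only among time points sharing the realized `(X_t, Z_t)` cell,
so every surrogate preserves each stratum's source multiset and hence
the conditional structure under the null. The default surrogate count is
50,000; tests run at 1,000–2,000 for speed. The p-value is
`(1 + #{surrogate ≥ observed}) / (1 + n_permutations)` — the add-one
rule avoids exact zeros, and ties count toward the surrogate tail
(conservative). A link is called significant when the observed TE
exceeds the surrogate distribution's 95th percentile (p < 0.05).

## Synthetic studies

The generator emulates the structure of the real sources: 48 units, 20
years of monthly data (240 months) by default; background checks per
capita around 0.0066 checks/person/month with a December-peaking
seasonal factor (relative amplitude 0.35) and log-normal scatter; a
suicide fraction near 0.55 with a slow linear trend; populations
log-normal around a few million with ~1%/year growth; centroids on a
deterministic continental-scale grid; ~10 low-response units (the least
populated), with respondent counts of 12–60 (H) or 1–9 (L) per year;
October anchors drawn binomially from the simulated truth (an
`infinite_respondents` switch yields exact anchors for recovery
studies); Poisson mass-shooting counts (0.5/month) and log-normal media
output, optionally event-coupled. Model parameters default to the
magnitudes estimated on the real panel (ρ = 0.163, σ² = 0.031, proxy
coefficients of order 18–70 per background check and 0.27–1.6 on the
suicide fraction, trend 0.0104/year); the proxy levels were chosen once
so the implied ownership sits in a realistic 0.3–0.4 band.

What passing tests show — and what they do not. Recovery studies
demonstrate that when the data-generating process *is* the model, the
concentrated-likelihood estimator finds it (each coefficient within 3
reported SEs in ≥ 90% of 100 replicates at study scale) and that the
permutation test is calibrated (null rejection ≈ 5%, uniform p-values)
and powerful against planted couplings. They do not validate the model's
adequacy for the real administrative data: real proxies have breaks,
policy shocks and measurement artifacts the generator omits, real survey
noise need not be binomial, and real spatial interaction need not follow
population-over-distance. With binomial anchor noise the 12-month-lag
regressor is itself noisy, so calibration on the default (noisy)
scenario absorbs survey sampling error into σ̂² — visible as σ̂² > σ²
there, and the reason recovery studies use exact anchors.

## Numerical choices and degenerate inputs

* ρ search interval shrunk to 99.9% of the spectral interval; optimizer
  tolerance 1e-8; convergence failures return `converged=False` with a
  message rather than raising.
* Exact log-determinant is the default for any panel whose yearly blocks
  fit in memory (they are n×n, so always at this problem's scale); the
  MC estimator is opt-in.
* Duplicate centroids, nonpositive populations, fractions outside
  [0, 1], non-consecutive months, and negative counts are rejected with
  errors naming the offending unit/cell. Fraction-range checks are
  enforced at the I/O boundary; directly constructed panels are
  shape-checked only, because noiseless simulated anchors may
  legitimately leave the unit interval.
* A constant series is a degenerate input to the unit-root check and is
  rejected; an empty permutation stratum is left untouched (nothing to
  shuffle); a singleton stratum likewise.
* First-month proxy lag: month 1 has no preceding month in the panel, so
  it reuses its own proxy value; the simulator and predictor share the
  convention, which is what makes exact self-consistency achievable.

## Known limitations

* Seasonal adjustment is classical decomposition, not an ARIMA-based
  signal extraction; series with moving seasonality are only
  approximately adjusted.
* The national aggregation reconstructs counts from rates when counts
  are unavailable, which weights the suicide fraction by population
  rather than by suicides.
* TE estimation is restricted to binary symbols and first-order
  embeddings; higher-order dependence is invisible to it.
* t-statistics rest on the asymptotic normality of the MLE at N ≈ 900;
  they are indicative, not exact, especially for ρ whose concentrated
  likelihood is flat at this scale.
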