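# Methods

## Model

An individual exposed in utero suffers an adverse outcome (the package's
"response") exactly when their radiation dose exceeds their own critical
dose: an all-or-none view of DNA repair in which all damage is repaired up
to an individual threshold and repair fails above it. Doses X₁ and
individual thresholds X₂ are independent lognormal random variables,

    X₁ ~ Lognormal(µ₁, σ₁),   X₂ ~ Lognormal(µ₂, σ₂),

with µ the natural log of the median and σ the log-scale standard
deviation. Units ride along as labels (mSv for doses, Bq/kg for body
burdens); no conversions are performed. Since log X₁ − log X₂ is normal,

    P(response) = P(X₁ > X₂) = Φ((µ₁ − µ₂) / √(σ₁² + σ₂²)),

and plotting this rate against the mean dose x̄ = exp(µ₁ + σ₁²/2) while µ₁
varies traces the cumulative lognormal Λ(x̄; µ, σ) with

    µ = µ₂ + σ₁²/2,    σ = √(σ₁² + σ₂²)

— an algebraic identity (substitute log x̄ = µ₁ + σ₁²/2), which the test
suite asserts to 1e-12. The model has no threshold: Λ is positive for every
positive dose. σ = 0 is the degenerate discrete-dose case, handled as a
point mass (unit-step cdf; the density is undefined and raises).

## Monte Carlo simulator

`simulate_exceedance` draws N paired (x₁, x₂) pinned to a
`numpy.random.Generator` stream, counts strict exceedances, and records
the realised mean dose. The dose sweep runs the comparison at k = 11 grid
values µ₁ = 0, 0.1, …, 1.0 with N = 10⁶ pairs per point and default
threshold parameters µ₂ = ln 10 ≈ 2.303, σ₂ = 0.4; each grid point uses a
freshly spawned child seed (`SeedSequence.spawn`), so points are
independent and the whole sweep is bit-reproducible from one seed. Event
counts are stored as exact integers; rates are always derived as
events/trials, never stored separately.

## Fitting

Both dose–response candidates — the cumulative lognormal Λ(x̄; µ, σ) and
the power law a·x̄ᵇ — are fitted to the (x̄, ȳ) sweep points by
iteratively reweighted nonlinear least squares:

    minimise  Σᵢ wᵢ (ȳᵢ − f(x̄ᵢ; θ))²,     wᵢ = Nᵢ / (ŷᵢ(1 − ŷᵢ)),

with binomial-variance weights recomputed from the *fitted* rates of the
current iterate (so zero-event points stay usable) and the inner weighted
problem solved by `scipy.optimize.least_squares`. At the rates involved
(≤ 10⁻²) these weights are numerically indistinguishable from Poisson
weights Nᵢ/ŷᵢ. The outer loop stops when the maximum relative parameter
change falls below 1e-8, capped at 50 iterations. σ and a are optimised on
the log scale to enforce positivity and reported on the natural scale with
delta-method standard errors. Initial values come from a probit-transform
linear regression of rates on log dose (lognormal) or ordinary least
squares on log–log points with ȳ > 0 (power law); an explicit (µ₀, σ₀) can
be supplied instead.

The converged weighted residual sum of squares is the **deviance**; with
the true rates supplied it averages exactly the number of points, and
models with equal df are ranked by it. Standard errors are the weighted
Gauss–Newton curvature at the optimum scaled by √(deviance/df); this
dispersion factor matches the magnitudes a standard weighted-`nls`
toolchain reports and is recorded in output metadata. Nested models are
compared by F = ((dev_r − dev_f)/Δdf)/(dev_f/df_f).

The with/without-dispersion table evaluates, at each sweep point's mean
dose, the fitted curve and the no-dispersion curve Λ(x̄; µ₂, σ₂); their
ratio quantifies the amplification of low-dose response by dose dispersion
(≈ 220-fold at the bottom of the default grid, ≈ 5.5-fold at the top).

The replicate study repeats the sweep-plus-fit pipeline (default 10
replicates on independent seed streams), collecting σ̂, its SE, and
z = (σ̂ − √(σ₁² + σ₂²))/SE, to verify the spread relation empirically.

## Epidemiological application stage

The dose–response form is applied to monthly perinatal mortality with the
cesium-137 body burden of pregnant women as the exposure, lagged seven
months (exposure around the second month of the pregnancies that end in
the index month):

    rate(t) = exp(b₀ + b₁t [+ annual sin/cos]) · (1 + A·Λ(C(t−7); µ, σ)),
    deaths(t) ~ Poisson(births(t) · rate(t)),

with Λ evaluated on log burden (µ in log Bq/kg). The multiplicative form
nests the cesium-free **reduced model** at A = 0 and makes the
observed/baseline rate ratio scatter around 1 + A·Λ, which is exactly the
plotted readout. The F-test of the cesium term compares the full fit
against a separately refit reduced model (Δdf = 3); the rate-ratio curve
instead divides observed rates by the full fit's own baseline with the
cesium factor switched off, so noise-free input reproduces 1 + A·Λ to
machine precision.

### Synthetic generator

No registry series is deposited, so the generator emulates one: 60 months
of 50,000 births, baseline 6 deaths per 1000 falling 2 %/year, and a
burden curve c(t) = peak·(t/t₀)²·exp(2(1 − t/t₀)) rising from zero at the
accident to 38 Bq/kg at t₀ = 12 months and decaying with a ~6-month
e-folding — the shape and sub-40 Bq/kg scale of post-Chernobyl body
burdens. The truth parameters default to µ = 3.97, σ = 0.30 (the published
real-data estimates) and amplitude A = 1.2, chosen so the peak rate ratio
is ≈ 1 + 1.2·Λ(38) ≈ 1.2, the scale of the published rate-ratio figure.
With ~300 deaths/month the Poisson noise per month is ~6 %, comparable to
that figure's error bars. The generator reproduces none of the features of
real registry data beyond these: no seasonality in the default truth, no
secular structure beyond the log-linear trend, no overdispersion, and
births held constant — so passing tests certify estimator behaviour under
the stated model, not performance on real registries.

### Identifiability and standard errors

With the burden peaking at 38 Bq/kg — below the median-effect burden
exp(3.97) ≈ 53 — only the lower flank of the sigmoid is observed, and the
Fisher information at the default truth gives corr(A, µ) ≈ 0.999: the
(A, µ, σ) surface is a long, multi-bowl ridge on which amplitude and
location trade off almost freely. Three numerical consequences are handled
explicitly:

- **Estimation** starts from a coarse profile search (baseline + amplitude
  fitted at fixed (µ, σ) over a grid) and the outer IRLS also accepts a
  deviance-stabilisation stopping rule (1e-9 relative), since parameters
  can drift along the flat ridge without changing the fit. A global
  profile scan over µ re-polishes the fit if it finds a better basin.
- **Standard errors** for (A, µ, σ) come from the profile deviance, not
  the local Gauss–Newton curvature (which understates ridge uncertainty
  severely). For µ the profile is scanned globally over its admissible
  range, minimising over all other parameters at each value with
  bidirectional warm-start continuation (a one-way sweep can ride an
  inferior branch of the multi-bowl surface and overstate the rise).
  Profile points are solved as weighted least squares but evaluated as the
  exact Poisson deviance 2Σ[m − d + d·log(d/m)], which is what the
  likelihood-ratio calibration applies to. The SE is half the larger
  one-sided distance from the estimate to the edge of the rise-≤ 4 region —
  the ±2·SE-equivalent region under the χ²₁ calibration, which needs no
  dispersion factor because the Poisson variance is known. A and σ use a
  rise-of-1 bracket around the optimum. Measured over two independent sets
  of 100 synthetic replicates, ±2 SE intervals for µ cover the truth
  96–98 % of the time; the curvature SEs managed ~50 %.
- **The identifiable functional** is the excess curve over the observed
  burden range. Readouts that depend only on it — the fitted rate-ratio
  curve and the practical threshold — are recovered tightly even when the
  individual parameters are not.

The null distribution of the cesium F-test is not exactly uniform: under
A = 0 the nuisance parameters (µ, σ) are unidentified, and profiling over
them inflates the deviance drop (the classical unidentified-nuisance
problem). Measured over 400 null replicates the test rejects at the 0.05
level ~7 % of the time; the acceptance checks therefore bound the
rejection rate rather than assert uniformity.

### Practical threshold

The cumulative-lognormal excess has no true threshold. The "practical"
threshold is the operational read-off point: the smallest burden C with
A·Λ(C; µ, σ) ≥ ε, i.e. exp(µ + σ·Φ⁻¹(ε/A)), with ε = 0.05 by default and
always reported alongside the value (ε is a CLI flag). It increases with ε,
tends to zero as ε → 0, and is +∞ when the fitted excess never reaches ε;
a non-positive fitted amplitude carries no threshold and raises.

## Problem sizes and numerical conventions

The test suite and acceptance script use the study-scale problem sizes
throughout: 11 × 10⁶ paired draws per sweep, 50 replicate sweeps for the
model-ranking check, 10 replicates for the σ-relation study, 100
effect-present and 400 null epi replicates. Fitted rates are clipped away
from {0, 1} by 1e-15 only inside weight computations; deviance weights are
never formed from observed rates. CSVs are written with round-trippable
float precision (`%.17g`) and read with round-trip parsing. Every CLI run
records its configuration, seed, and library versions in a metadata JSON
next to its outputs; plots are optional artifacts and never inputs.

## Known limitations

- The closed-form exceedance identity is exact only under independence of
  dose and threshold; correlated draws are out of scope.
- The epi stage's parameters (A, µ, σ) are jointly weakly identified
  whenever the burden never reaches the median-effect level; results
  should be read through the identifiable functionals (rate-ratio curve,
  practical threshold).
- The cesium F-test is mildly anticonservative under the null (see above).
- Variance-reduction techniques, alternative tolerance distributions
  (probit/logit on linear dose, Weibull), and dose-rate conversions are
  deliberately not implemented.
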