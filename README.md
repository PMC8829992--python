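# logndose

Tolerance-distribution modelling of teratogenic radiation dose–response:
Monte Carlo threshold-exceedance simulation, cumulative-lognormal versus
power-law curve fitting, and a synthetic epidemiological application with a
lagged cesium-burden excess on perinatal mortality.

## The scientific problem

Radiation-protection guidance holds that teratogenic effects (stillbirth,
perinatal death, birth defects after in-utero exposure) do not occur below a
threshold dose of ~100 mSv, a figure derived from mouse experiments at
discrete doses in the Gray range. Epidemiological series after Chernobyl,
however, show effects at population doses orders of magnitude lower. The
model implemented here explains how both can be true at once: if each
individual responds only when their dose exceeds their own critical dose
(an all-or-none repair-failure threshold), and **both** doses X₁ and
individual thresholds X₂ are lognormally distributed across the population,

- X₁ ~ Lognormal(µ₁, σ₁)  (dose distribution, µ = log median),
- X₂ ~ Lognormal(µ₂, σ₂)  (threshold / radiosensitivity distribution),

then the population response rate is the exceedance probability

  P(X₁ > X₂) = Φ((µ₁ − µ₂) / √(σ₁² + σ₂²)),

and the dose–response curve — response rate against mean dose
x̄ = exp(µ₁ + σ₁²/2) — is itself a **cumulative lognormal with no
threshold**, with location µ = µ₂ + σ₁²/2 and spread σ = √(σ₁² + σ₂²).
Dose *dispersion* (σ₁ > 0) amplifies low-dose response rates by orders of
magnitude relative to discrete doses, which is why whole-population data can
show effects far below the apparent threshold of homogeneous-dose animal
experiments.

The package provides:

- `logndose.core` — the lognormal primitives and the closed-form exceedance
  and derived-curve algebra (the analytic oracles);
- `logndose.simulate` — the seeded Monte Carlo exceedance simulator, the
  11-point µ₁ dose sweep, and the replicate study verifying
  σ = √(σ₁² + σ₂²);
- `logndose.fitting` — iteratively reweighted nonlinear least squares for
  the cumulative-lognormal and power-law (a·x̄ᵇ) mean functions, weighted
  deviance, model comparison, F-tests, and with/without-dispersion ratio
  tables;
- `logndose.epi` — the application stage: monthly perinatal-mortality
  series with a multiplicative excess 1 + A·Λ(C(t−7); µ, σ) driven by the
  cesium-137 body burden of pregnant women seven months earlier, a
  synthetic post-accident generator, rate-ratio readouts, and the
  ε-convention "practical threshold";
- a `logndose` command-line tool tying the stages together.

## Worked example

Simulate the default dose sweep (µ₁ = 0, 0.1, …, 1.0, σ₁ = 0.3,
threshold distribution Lognormal(ln 10, 0.4), one million paired draws per
point) and fit both candidate curves:

```python
import logndose as ld

sweep = ld.run_sweep(ld.SweepConfig(sigma1=0.3, seed=1))
logn  = ld.fit_cumulative_lognormal(sweep)
power = ld.fit_power_law(sweep)
print(logn.estimates, logn.deviance)
print(power.estimates["b"], power.deviance)
```

prints (seed 1)

```
{'mu': 2.335354525412398, 'sigma': 0.4949081634327268} 4.781923080843357
6.760538568736572 53.56023419803937
```

The fitted location 2.335 and spread 0.495 agree with the derived relations
µ₂ + σ₁²/2 = 2.348 and √(0.3² + 0.4²) = 0.5 within the standard errors
(±0.011, ±0.004), and the cumulative lognormal fits far better than the
power law (deviance 4.8 vs 53.6 at 9 degrees of freedom each). The same run
from the shell:

```sh
logndose sweep --sigma1 0.3 --seed 1 --out out/
logndose fit out/sweep.csv --model both --table --out out/
```

The epidemiological stage generates and fits a synthetic 60-month series
(50,000 births/month, baseline 6 deaths per 1000 falling ~2 %/year, burden
peaking at 38 Bq/kg):

```sh
logndose epi-run --seed 3 --out out/epi/
```

```
mu=5.638±1.351, sigma=1.185±0.642, amplitude=4.124, p_cesium=0.00072
practical threshold (epsilon=0.05): 19.4 Bq/kg
```

The cesium term is highly significant and the practical threshold — the
burden at which the fitted relative excess reaches ε = 5 % — is tightly
determined, while the individual curve parameters (A, µ, σ) carry large
profile standard errors: only the lower flank of the sigmoid is observed
when the burden never exceeds the median-effect level (see
`docs/methods.md` on identifiability).

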