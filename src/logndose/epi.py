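"""Lagged cumulative-lognormal excess risk on perinatal-mortality series.

The application stage models monthly perinatal mortality as a log-linear
secular baseline times a multiplicative excess driven by the cesium-137
body burden of pregnant women seven months earlier:

    rate(t) = exp(b0 + b1*t [+ seasonal]) * (1 + A * Lambda(C(t - lag); mu, sigma)),
    deaths(t) ~ Poisson(births(t) * rate(t)),

where Lambda is the lognormal cdf on burden (mu in log Bq/kg) and A is the
amplitude of the excess at saturating burden.  The reduced model fixes
A = 0 and is the denominator of the observed/predicted rate-ratio readout.

No registry data are deposited, so a synthetic generator stands in for the
post-accident series: a burden curve rising from ~0 to a peak below
40 Bq/kg and then decaying, a baseline of ~6 perinatal deaths per 1000
births falling ~2 %/year, and Poisson observation noise.  Defaults put the
peak rate ratio near 1.2.  Parameter recovery on this generator — not
reproduction of registry numbers — is what the test suite checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import optimize
from scipy.special import ndtr, ndtri

__all__ = [
    "EpiRecord",
    "EpiModelSpec",
    "EpiTruth",
    "EpiFitResult",
    "RateRatioPoint",
    "default_burden_curve",
    "generate_epi_series",
    "fit_epi_model",
    "rate_ratio_curve",
    "practical_threshold",
]

MAX_OUTER_ITERATIONS = 50
PARAM_TOL = 1e-8
MAX_AMPLITUDE = 1e6  # overflow guard only; the amplitude is effectively unbounded


@dataclass(frozen=True)
class EpiRecord:
    """One period (month) of births, perinatal deaths, and cesium body burden (Bq/kg)."""

    period: int
    births: int
    deaths: int
    burden: float

    def __post_init__(self) -> None:
        if self.births <= 0:
            raise ValueError("births must be positive")
        if not (0 <= self.deaths <= self.births):
            raise ValueError("deaths must lie in [0, births]")
        if self.burden < 0.0:
            raise ValueError("burden must be >= 0")

    @property
    def rate(self) -> float:
        return self.deaths / self.births


@dataclass(frozen=True)
class EpiModelSpec:
    """Structure of the mortality regression: exposure lag and baseline terms.

    The baseline always contains an intercept and a linear trend in month;
    ``seasonality`` adds one annual sin/cos pair.  The excess term is fixed
    as the multiplicative cumulative lognormal described in the module
    docstring.
    """

    lag: int = 7
    seasonality: bool = False

    def __post_init__(self) -> None:
        if self.lag < 0:
            raise ValueError("lag must be >= 0")

    @property
    def n_baseline(self) -> int:
        return 4 if self.seasonality else 2


@dataclass(frozen=True)
class EpiTruth:
    """Generator ground truth for one synthetic series.

    ``baseline_per_1000`` is the month-0 perinatal mortality rate;
    ``trend_per_month`` the log-linear secular slope (default -2 %/year);
    ``amplitude`` the saturating relative excess A; ``mu``/``sigma`` the
    cumulative-lognormal parameters on log Bq/kg.
    """

    baseline_per_1000: float = 6.0
    trend_per_month: float = math.log(0.98) / 12.0
    amplitude: float = 1.2
    mu: float = 3.97
    sigma: float = 0.30

    def __post_init__(self) -> None:
        if self.baseline_per_1000 <= 0:
            raise ValueError("baseline rate must be positive")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0 for generation")


@dataclass(frozen=True)
class EpiFitResult:
    """Full-model estimates plus the nested amplitude-0 refit.

    ``baseline_coefficients`` holds the full model's intercept/trend (and
    seasonal pair); ``reduced_coefficients``/``reduced_deviance`` describe
    the separately refit A = 0 model used by the F-test ``p_cesium``.
    """

    baseline_coefficients: dict[str, float]
    amplitude: float
    mu: float
    sigma: float
    standard_errors: dict[str, float]
    deviance: float
    df: int
    p_cesium: float
    converged: bool
    n_iterations: int
    lag: int
    reduced_coefficients: dict[str, float]
    reduced_deviance: float
    reduced_df: int


@dataclass(frozen=True)
class RateRatioPoint:
    """Observed/baseline-predicted mortality ratio at one lagged burden value.

    ``sd`` is the delta-method one-standard-deviation error ratio/sqrt(deaths);
    it is NaN (and ``flagged`` True) for zero-death periods.
    """

    burden: float
    ratio: float
    sd: float
    flagged: bool = False


def default_burden_curve(
    n: int,
    peak: float = 38.0,
    t_peak: float = 12.0,
    shape: float = 2.0,
) -> np.ndarray:
    """Post-accident cesium body-burden curve (Bq/kg) of length ``n``.

    Gamma-like pulse c(t) = peak * (t/t_peak)^shape * exp(shape*(1 - t/t_peak)):
    zero at the accident month, maximum ``peak`` at ``t_peak`` months, then an
    exponential decay with e-folding time t_peak/shape, emulating the rise
    and clearance of Cs-137 burden in a population after fallout.
    """
    t = np.arange(n, dtype=float)
    r = t / t_peak
    return peak * r**shape * np.exp(shape * (1.0 - r))


def _lagged_burden_from_curve(burden_curve: np.ndarray, n_months: int, lag: int) -> np.ndarray:
    """Burden acting on month t, i.e. the burden ``lag`` months before t."""
    return np.asarray(burden_curve, dtype=float)[:n_months]


def _excess_factor(burden: np.ndarray, amplitude: float, mu: float, sigma: float) -> np.ndarray:
    lam = np.zeros_like(burden)
    pos = burden > 0.0
    lam[pos] = ndtr((np.log(burden[pos]) - mu) / sigma)
    return 1.0 + amplitude * lam


def generate_epi_series(
    truth: EpiTruth = EpiTruth(),
    spec: EpiModelSpec = EpiModelSpec(),
    n_months: int = 60,
    births_per_month: int = 50_000,
    burden_curve: Sequence[float] | None = None,
    seed=0,
) -> list[EpiRecord]:
    """Simulate a monthly perinatal-mortality series with a lagged burden effect.

    ``burden_curve`` must cover ``n_months + spec.lag`` entries; index i is
    the population burden at month i - lag, so entry t is the burden that
    acts on the month-t death rate and entry t + lag is the burden measured
    in month t itself (stored in the record).  The default curve starts at
    the accident and peaks below 40 Bq/kg.
    """
    if burden_curve is None:
        burden_curve = default_burden_curve(n_months + spec.lag)
    burden_curve = np.asarray(burden_curve, dtype=float)
    if len(burden_curve) < n_months + spec.lag:
        raise ValueError(
            f"burden_curve must have at least n_months + lag = {n_months + spec.lag} entries"
        )
    if np.any(burden_curve < 0.0):
        raise ValueError("burden_curve must be non-negative")

    t = np.arange(n_months, dtype=float)
    baseline = (truth.baseline_per_1000 / 1000.0) * np.exp(truth.trend_per_month * t)
    acting = _lagged_burden_from_curve(burden_curve, n_months, spec.lag)
    rate = baseline * _excess_factor(acting, truth.amplitude, truth.mu, truth.sigma)
    if np.any(rate < 0.0):
        raise ValueError("configured truth implies negative rates")

    rng = np.random.default_rng(seed)
    deaths = rng.poisson(births_per_month * rate)
    own_burden = burden_curve[spec.lag : spec.lag + n_months]
    return [
        EpiRecord(period=int(i), births=births_per_month, deaths=int(d), burden=float(c))
        for i, (d, c) in enumerate(zip(deaths, own_burden))
    ]


def _design(records: Sequence[EpiRecord], spec: EpiModelSpec):
    """Trim the first ``lag`` periods and assemble arrays for fitting.

    Returns (t, births, y, lagged_burden) where the lagged burden of the
    record at position i is the burden stored ``lag`` records earlier.
    """
    lag = spec.lag
    if len(records) - lag < spec.n_baseline + 3 + 3:
        raise ValueError("series too short for the lag and parameter count")
    t = np.array([r.period for r in records[lag:]], dtype=float)
    births = np.array([r.births for r in records[lag:]], dtype=float)
    y = np.array([r.rate for r in records[lag:]], dtype=float)
    lagged = np.array([r.burden for r in records[: len(records) - lag]], dtype=float)
    return t, births, y, lagged


def _baseline_fn(t: np.ndarray, coef: np.ndarray, seasonality: bool) -> np.ndarray:
    eta = coef[0] + coef[1] * t
    if seasonality:
        w = 2.0 * math.pi * t / 12.0
        eta = eta + coef[2] * np.sin(w) + coef[3] * np.cos(w)
    return np.exp(np.clip(eta, -700.0, 50.0))


def _poisson_irls(t, births, y, mean_fn, theta0, bounds):
    """IRLS with Poisson-variance weights w = births / yhat for rate data.

    Converged when the parameters stabilise or, on a flat likelihood ridge
    where parameters drift without changing the fit, when the deviance
    itself stabilises between reweighting steps.
    """
    theta = np.asarray(theta0, dtype=float)
    converged = False
    n_outer = 0
    dev_prev = math.inf
    for n_outer in range(1, MAX_OUTER_ITERATIONS + 1):
        yhat = np.maximum(mean_fn(t, theta), 1e-15)
        sqrt_w = np.sqrt(births / yhat)
        sol = optimize.least_squares(
            lambda th: sqrt_w * (y - mean_fn(t, th)),
            theta,
            bounds=bounds,
            method="trf",
            xtol=1e-12,
            ftol=1e-12,
            gtol=1e-12,
        )
        delta = np.max(np.abs(sol.x - theta) / np.maximum(np.abs(theta), 1e-12))
        theta = sol.x
        dev_now = 2.0 * float(sol.cost)
        if delta < PARAM_TOL or abs(dev_now - dev_prev) <= 1e-9 * max(dev_now, 1.0):
            converged = True
            break
        dev_prev = dev_now
    yhat = np.maximum(mean_fn(t, theta), 1e-15)
    w = births / yhat
    deviance = float(np.sum(w * (y - yhat) ** 2))
    df = len(y) - len(theta)
    jtj = sol.jac.T @ sol.jac
    try:
        cov = np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        cov = np.full_like(jtj, np.nan)
    if df > 0 and deviance > 0:
        cov = cov * (deviance / df)
    return theta, cov, deviance, df, converged, n_outer


class _Nested:
    """Minimal deviance/df carrier for f_test."""

    def __init__(self, deviance: float, df: int):
        self.deviance = deviance
        self.df = df


def fit_epi_model(
    records: Sequence[EpiRecord],
    spec: EpiModelSpec = EpiModelSpec(),
    compute_se: bool = True,
) -> EpiFitResult:
    """Fit the full (baseline x excess) and reduced (baseline-only) models.

    The first ``lag`` periods are dropped (their lagged burden precedes the
    series).  Both models are fitted by iteratively reweighted least squares
    with Poisson-variance weights; ``p_cesium`` is the F-test of the three
    excess parameters (A, mu, sigma).  ``compute_se=False`` skips the
    profile-deviance standard errors of the excess parameters (the expensive
    part) and reports them as NaN; estimates, deviances, and the F-test are
    unaffected.
    """
    from .fitting import f_test

    t, births, y, lagged = _design(records, spec)
    if np.ptp(lagged) == 0.0:
        raise ValueError("burden has no variation; amplitude is unidentifiable")
    seasonal = spec.seasonality
    nb = spec.n_baseline

    # reduced model: log-linear baseline only
    slope, intercept = np.polyfit(t, np.log(np.maximum(y, 1e-8)), 1)
    theta0_red = np.array([intercept, slope] + ([0.0, 0.0] if seasonal else []))

    def mean_red(tv, th):
        return _baseline_fn(tv, th, seasonal)

    red_theta, _, red_dev, red_df, red_conv, _ = _poisson_irls(
        t, births, y, mean_red, theta0_red, (-np.inf, np.inf)
    )

    # full model: baseline coefficients, then (A, mu, log sigma).  (mu, sigma)
    # trade off against A along a flat ridge when the burden never reaches the
    # median-effect level, so the start point comes from a coarse profile
    # search: fit baseline + amplitude at fixed (mu, sigma) over a grid and
    # polish the best grid point with the full IRLS.
    pos = lagged > 0.0
    if not pos.any():
        raise ValueError("burden is zero throughout; amplitude is unidentifiable")
    log_cmax = math.log(lagged.max())
    mu_lo, mu_hi = log_cmax - 3.0, log_cmax + 2.0
    lo = np.concatenate([np.full(nb, -np.inf), [-0.999, mu_lo, math.log(0.02)]])
    hi = np.concatenate([np.full(nb, np.inf), [MAX_AMPLITUDE, mu_hi, math.log(5.0)]])

    def mean_full(tv, th):
        base = _baseline_fn(tv, th[:nb], seasonal)
        return base * _excess_factor(lagged, th[nb], th[nb + 1], math.exp(th[nb + 2]))

    sqrt_w0 = np.sqrt(births / np.maximum(mean_red(t, red_theta), 1e-15))
    best_sse, best_start = math.inf, None
    for mu_c in np.linspace(mu_lo + 0.5, mu_hi - 0.5, 7):
        for sigma_c in (0.1, 0.2, 0.3, 0.5, 0.8):
            lam = _excess_factor(lagged, 1.0, mu_c, sigma_c) - 1.0

            def mean_profile(tv, th):
                return _baseline_fn(tv, th[:nb], seasonal) * (1.0 + th[nb] * lam)

            sol = optimize.least_squares(
                lambda th: sqrt_w0 * (y - mean_profile(t, th)),
                np.concatenate([red_theta, [0.1]]),
                bounds=(
                    np.concatenate([np.full(nb, -np.inf), [-0.999]]),
                    np.concatenate([np.full(nb, np.inf), [MAX_AMPLITUDE]]),
                ),
                method="trf",
                xtol=1e-10,
                ftol=1e-10,
            )
            if sol.cost < best_sse:
                best_sse = sol.cost
                best_start = np.concatenate([sol.x, [mu_c, math.log(sigma_c)]])

    theta0_full = np.concatenate(
        [best_start[:nb], [best_start[nb], best_start[nb + 1], best_start[nb + 2]]]
    )
    theta, cov, deviance, df, converged, n_iter = _poisson_irls(
        t, births, y, mean_full, theta0_full, (lo, hi)
    )

    names = ["intercept", "trend"] + (["sin", "cos"] if seasonal else [])
    sigma_hat = float(math.exp(theta[nb + 2]))
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    standard_errors = {nm: float(se[i]) for i, nm in enumerate(names)}

    # SEs for the excess parameters come from the profile deviance, not the
    # local curvature: along the A-mu ridge the surface is a chain of shallow
    # bowls and curvature SEs grossly understate the uncertainty.  Profile
    # points are solved as weighted least squares (fast) but *evaluated* as
    # the exact Poisson deviance, which is what the chi-square calibration
    # of the likelihood-ratio region applies to.
    yhat_fit = np.maximum(mean_full(t, theta), 1e-15)
    sqrt_w_fit = np.sqrt(births / yhat_fit)
    deaths_obs = y * births

    def _poisson_dev(rate_hat: np.ndarray) -> float:
        m = np.maximum(births * rate_hat, 1e-12)
        with np.errstate(divide="ignore", invalid="ignore"):
            log_term = np.where(deaths_obs > 0, deaths_obs * np.log(deaths_obs / m), 0.0)
        return 2.0 * float(np.sum(m - deaths_obs + log_term))

    def _fixed_mu_dev(mu_c: float, starts: list[np.ndarray]):
        """Minimum over (baseline, A, sigma) at fixed mu, best of the given starts."""
        best_cost, best_th = math.inf, None

        def mean_at(th):
            base = _baseline_fn(t, th[:nb], seasonal)
            return base * _excess_factor(lagged, th[nb], mu_c, math.exp(th[nb + 1]))

        for th0 in starts:
            sol = optimize.least_squares(
                lambda th: sqrt_w_fit * (y - mean_at(th)),
                th0,
                bounds=(
                    np.concatenate([np.full(nb, -np.inf), [-0.999, math.log(0.02)]]),
                    np.concatenate([np.full(nb, np.inf), [MAX_AMPLITUDE, math.log(5.0)]]),
                ),
                method="trf",
                xtol=1e-8,
                ftol=1e-8,
            )
            if sol.cost < best_cost:
                best_cost, best_th = sol.cost, sol.x
        return _poisson_dev(mean_at(best_th)), best_th

    # profile deviance of mu over its whole admissible range, warm-started by
    # continuation from the neighbouring grid point plus the fitted optimum;
    # the finer grid is only needed when the profile also yields the SEs
    mu_grid = np.linspace(mu_lo + 0.1, mu_hi - 0.1, 21 if compute_se else 11)
    prof = np.empty_like(mu_grid)
    prof_theta: list[np.ndarray] = []
    at_optimum = np.concatenate([theta[:nb], [theta[nb], theta[nb + 2]]])
    sigma_starts = [
        np.concatenate([theta[:nb], [max(theta[nb], 0.0), math.log(s)]])
        for s in (0.1, 0.3, 0.8, 2.0)
    ]
    for j, mu_c in enumerate(mu_grid):
        starts = [at_optimum] + sigma_starts if j == 0 else [prof_theta[-1], at_optimum]
        prof[j], th_j = _fixed_mu_dev(float(mu_c), starts)
        prof_theta.append(th_j)
    # second continuation pass in the opposite direction: a one-way sweep can
    # ride an inferior branch of the multi-bowl surface for a stretch of mu
    for j in range(len(mu_grid) - 2, -1, -1):
        d_back, th_back = _fixed_mu_dev(float(mu_grid[j]), [prof_theta[j + 1]])
        if d_back < prof[j]:
            prof[j], prof_theta[j] = d_back, th_back

    # if the scan finds a better basin than the polished fit, refit from there
    j_min = int(np.argmin(prof))
    if prof[j_min] < _poisson_dev(mean_full(t, theta)) - 1e-3:
        th_j = prof_theta[j_min]
        restart = np.concatenate([th_j[:nb], [th_j[nb], mu_grid[j_min], th_j[nb + 1]]])
        theta, cov, deviance, df, converged, n_iter = _poisson_irls(
            t, births, y, mean_full, restart, (lo, hi)
        )
        sigma_hat = float(math.exp(theta[nb + 2]))
        yhat_fit = np.maximum(mean_full(t, theta), 1e-15)
        sqrt_w_fit = np.sqrt(births / yhat_fit)
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
        standard_errors = {nm: float(se[i]) for i, nm in enumerate(names)}

    dev0 = _poisson_dev(mean_full(t, theta))

    def _mu_profile_se() -> float:
        """SE equivalent of the profile-likelihood interval for mu.

        The region where the profile deviance rises by at most 4 is the
        +-2 SE region by the likelihood-ratio calibration (which survives the
        strong non-quadraticity of this profile; the chi-square cut needs no
        dispersion factor because the Poisson variance is fully known); the
        SE is the larger one-sided distance from the estimate to its edge,
        divided by 2.
        """
        cut = min(dev0, float(prof.min())) + 4.0
        mu_hat = float(theta[nb + 1])
        below = prof <= cut
        if not below.any():
            return 0.5 * float(mu_grid[1] - mu_grid[0])  # narrower than the grid step
        left = float(mu_grid[below][0])
        right = float(mu_grid[below][-1])
        # refine both edges by linear interpolation against the neighbour point
        idx = np.flatnonzero(below)
        if idx[0] > 0:
            j = idx[0]
            f = (cut - prof[j]) / max(prof[j - 1] - prof[j], 1e-300)
            left = float(mu_grid[j] - f * (mu_grid[j] - mu_grid[j - 1]))
        if idx[-1] < len(mu_grid) - 1:
            j = idx[-1]
            f = (cut - prof[j]) / max(prof[j + 1] - prof[j], 1e-300)
            right = float(mu_grid[j] + f * (mu_grid[j + 1] - mu_grid[j]))
        return max(right - mu_hat, mu_hat - left, mu_grid[1] - mu_grid[0]) / 2.0

    def _profile_dev(idx: int, value: float) -> float:
        free = [i for i in range(len(theta)) if i != idx]

        def resid(th_free):
            th = np.empty_like(theta)
            th[free] = th_free
            th[idx] = value
            return sqrt_w_fit * (y - mean_full(t, th))

        sol = optimize.least_squares(
            resid, theta[free], bounds=(lo[free], hi[free]), method="trf",
            xtol=1e-10, ftol=1e-10,
        )
        th = np.empty_like(theta)
        th[free] = sol.x
        th[idx] = value
        return _poisson_dev(mean_full(t, th))

    def _profile_se(idx: int, h0: float, hmax: float) -> float:
        """Half-width at which the profile deviance rises by 1 (one SE)."""
        sides = []
        for sign in (1.0, -1.0):
            h_prev, d_prev, h, side = 0.0, 0.0, h0, None
            while h <= hmax:
                value = float(np.clip(theta[idx] + sign * h, lo[idx], hi[idx]))
                rise = _profile_dev(idx, value) - dev0
                if rise >= 1.0:
                    side = h_prev + (h - h_prev) * (1.0 - d_prev) / max(rise - d_prev, 1e-300)
                    break
                if value in (lo[idx], hi[idx]):
                    break
                h_prev, d_prev, h = h, rise, 2.0 * h
            sides.append(side if side is not None else hmax)
        return 0.5 * (sides[0] + sides[1])

    a_hat = float(theta[nb])
    if compute_se:
        standard_errors["amplitude"] = _profile_se(nb, max(0.25, 0.5 * abs(a_hat)), max(16.0, 16.0 * abs(a_hat)))
        standard_errors["mu"] = _mu_profile_se()
        standard_errors["sigma"] = sigma_hat * _profile_se(nb + 2, 0.2, 4.0)  # delta method
    else:
        standard_errors["amplitude"] = math.nan
        standard_errors["mu"] = math.nan
        standard_errors["sigma"] = math.nan

    p_cesium = f_test(_Nested(deviance, df), _Nested(red_dev, red_df))
    return EpiFitResult(
        baseline_coefficients={nm: float(theta[i]) for i, nm in enumerate(names)},
        amplitude=float(theta[nb]),
        mu=float(theta[nb + 1]),
        sigma=sigma_hat,
        standard_errors=standard_errors,
        deviance=deviance,
        df=df,
        p_cesium=p_cesium,
        converged=bool(converged and red_conv),
        n_iterations=n_iter,
        lag=spec.lag,
        reduced_coefficients={nm: float(red_theta[i]) for i, nm in enumerate(names)},
        reduced_deviance=red_dev,
        reduced_df=red_df,
    )


def rate_ratio_curve(records: Sequence[EpiRecord], fit: EpiFitResult) -> list[RateRatioPoint]:
    """Observed rate over the cesium-free baseline of the full fit, per period.

    The denominator is the full model's fitted baseline with the cesium
    factor switched off, so on noise-free input the ratios trace
    1 + A*Lambda(burden; mu, sigma) exactly.  Points are keyed by lagged
    burden; zero-death periods get a NaN sd and are flagged.
    """
    if not fit.converged:
        raise ValueError("rate_ratio_curve requires a converged fit")
    spec = EpiModelSpec(lag=fit.lag, seasonality="sin" in fit.baseline_coefficients)
    t, births, y, lagged = _design(records, spec)
    coef = np.array([fit.baseline_coefficients[k] for k in fit.baseline_coefficients])
    baseline = _baseline_fn(t, coef, spec.seasonality)
    deaths = y * births
    points = []
    for burden_i, y_i, base_i, d_i in zip(lagged, y, baseline, deaths):
        ratio = y_i / base_i
        if d_i > 0:
            points.append(RateRatioPoint(float(burden_i), float(ratio), float(ratio / math.sqrt(d_i))))
        else:
            points.append(RateRatioPoint(float(burden_i), float(ratio), math.nan, flagged=True))
    return points


def practical_threshold(fit: EpiFitResult, epsilon: float = 0.05) -> float:
    """Smallest burden whose fitted relative excess A*Lambda reaches ``epsilon``.

    The cumulative-lognormal excess has no true threshold; this is the
    operational reading-off point exp(mu + sigma * Phi^-1(epsilon/A)),
    increasing in epsilon.  Returns +inf when the excess never reaches
    epsilon; an amplitude <= 0 carries no threshold at all and raises.
    """
    if epsilon <= 0.0:
        raise ValueError("epsilon must be positive")
    if fit.amplitude <= 0.0:
        raise ValueError("no practical threshold: fitted amplitude is not positive")
    q = epsilon / fit.amplitude
    if q >= 1.0:
        return math.inf
    return math.exp(fit.mu + fit.sigma * float(ndtri(q)))
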