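"""Monte Carlo threshold-exceedance simulation.

Each trial draws one dose and one individual threshold from independent
lognormal distributions; the trial is an adverse outcome when the dose
exceeds the threshold.  A dose sweep repeats this for a grid of dose-median
parameters mu1 (default 0, 0.1, ..., 1.0 with N = 1e6 trials each, fresh
draws per grid point) and records the event count and the realised mean
dose, producing the (mean dose, response rate) points that the curve
fitters consume.  The replicate study re-runs the whole sweep-plus-fit
pipeline to verify the spread relation sigma = sqrt(sigma1^2 + sigma2^2)
empirically.

All randomness flows from a single integer seed (or a
``numpy.random.SeedSequence``); child streams are spawned per grid point
and per replicate, so runs are reproducible bit-for-bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .core import LognormalParams

__all__ = [
    "SweepConfig",
    "SweepPoint",
    "ReplicateStudyResult",
    "simulate_exceedance",
    "run_sweep",
    "replicate_sigma_study",
]

DEFAULT_MU1_GRID: tuple[float, ...] = tuple(round(0.1 * i, 1) for i in range(11))
DEFAULT_THRESHOLD = LognormalParams(mu=math.log(10.0), sigma=0.4)


def _seed_sequence(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    if isinstance(seed, (int, np.integer)):
        return np.random.SeedSequence(int(seed))
    raise ValueError(f"seed must be an int or SeedSequence, got {type(seed).__name__}")


@dataclass(frozen=True)
class SweepConfig:
    """Configuration of one dose sweep.

    ``mu1_grid`` must be strictly increasing; ``sigma1`` is the common
    log-scale dose dispersion; ``threshold`` the population distribution of
    individual threshold doses; ``n_trials`` the number of paired draws per
    grid point.
    """

    mu1_grid: tuple[float, ...] = DEFAULT_MU1_GRID
    sigma1: float = 0.3
    threshold: LognormalParams = DEFAULT_THRESHOLD
    n_trials: int = 1_000_000
    seed: object = 0

    def __post_init__(self) -> None:
        if len(self.mu1_grid) == 0:
            raise ValueError("mu1_grid must not be empty")
        if any(b <= a for a, b in zip(self.mu1_grid, self.mu1_grid[1:])):
            raise ValueError("mu1_grid must be strictly increasing")
        if self.sigma1 < 0.0:
            raise ValueError(f"sigma1 must be >= 0, got {self.sigma1}")
        if not (isinstance(self.n_trials, (int, np.integer)) and self.n_trials >= 1):
            raise ValueError(f"n_trials must be a positive integer, got {self.n_trials}")
        _seed_sequence(self.seed)  # validates


@dataclass(frozen=True)
class SweepPoint:
    """One simulated grid point: mu1, realised mean dose, events out of trials."""

    mu1: float
    mean_dose: float
    events: int
    trials: int

    def __post_init__(self) -> None:
        if not (0 <= self.events <= self.trials):
            raise ValueError("events must lie in [0, trials]")
        if not (self.mean_dose > 0.0):
            raise ValueError("mean_dose must be positive")

    @property
    def rate(self) -> float:
        """Observed response rate events/trials (exact; never stored separately)."""
        return self.events / self.trials


@dataclass(frozen=True)
class ReplicateStudyResult:
    """Spread estimates from repeated sweep-plus-fit replicates.

    ``z_scores[i] = (sigma_hats[i] - sigma_expected) / ses[i]`` and
    ``mean_deviation = mean(sigma_hats) - sigma_expected`` with standard
    error ``sd(sigma_hats)/sqrt(n_reps)``.
    """

    sigma_expected: float
    sigma_hats: tuple[float, ...]
    ses: tuple[float, ...]
    z_scores: tuple[float, ...]
    mean_deviation: float
    se_mean_deviation: float
    n_failed: int = 0


def draw_lognormal(params: LognormalParams, n: int, rng: np.random.Generator) -> np.ndarray:
    """n draws from lognormal(mu, sigma); a constant array exp(mu) when sigma = 0."""
    if params.is_degenerate:
        return np.full(n, params.median)
    return rng.lognormal(mean=params.mu, sigma=params.sigma, size=n)


def simulate_exceedance(
    dose: LognormalParams,
    threshold: LognormalParams,
    n_trials: int,
    seed,
) -> tuple[int, float]:
    """Count dose > threshold over ``n_trials`` independent paired draws.

    Returns ``(events, mean_dose)`` where ``mean_dose`` is the sample mean
    of the dose draws.  Deterministic given the seed.
    """
    if not (isinstance(n_trials, (int, np.integer)) and n_trials >= 1):
        raise ValueError(f"n_trials must be a positive integer, got {n_trials}")
    rng = np.random.default_rng(_seed_sequence(seed))
    x1 = draw_lognormal(dose, int(n_trials), rng)
    x2 = draw_lognormal(threshold, int(n_trials), rng)
    events = int(np.count_nonzero(x1 > x2))
    return events, float(x1.mean())


def run_sweep(config: SweepConfig) -> list[SweepPoint]:
    """Simulate one sweep: one SweepPoint per mu1 grid value, fresh draws each.

    Child seeds are spawned from ``config.seed`` in grid order, so the full
    sweep is reproducible and grid points are statistically independent.
    """
    children = _seed_sequence(config.seed).spawn(len(config.mu1_grid))
    points = []
    for mu1, child in zip(config.mu1_grid, children):
        dose = LognormalParams(mu=mu1, sigma=config.sigma1)
        events, mean_dose = simulate_exceedance(dose, config.threshold, config.n_trials, child)
        points.append(SweepPoint(mu1=mu1, mean_dose=mean_dose, events=events, trials=config.n_trials))
    return points


def replicate_sigma_study(
    config: SweepConfig,
    n_reps: int,
    fit: Callable[[Sequence[SweepPoint]], "FitResult"] | None = None,
) -> ReplicateStudyResult:
    """Repeat the sweep ``n_reps`` times, fit each, and test sigma = sqrt(s1^2+s2^2).

    Each replicate uses an independently spawned seed stream.  ``fit``
    defaults to the package's iteratively reweighted cumulative-lognormal
    fitter; a replicate whose fit does not converge is excluded and counted
    in ``n_failed``.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if fit is None:
        from .fitting import fit_cumulative_lognormal

        fit = fit_cumulative_lognormal
    sigma_expected = math.sqrt(config.sigma1**2 + config.threshold.sigma**2)

    sigma_hats, ses, n_failed = [], [], 0
    for child in _seed_sequence(config.seed).spawn(n_reps):
        rep_config = SweepConfig(
            mu1_grid=config.mu1_grid,
            sigma1=config.sigma1,
            threshold=config.threshold,
            n_trials=config.n_trials,
            seed=child,
        )
        result = fit(run_sweep(rep_config))
        if not result.converged:
            n_failed += 1
            continue
        sigma_hats.append(result.estimates["sigma"])
        ses.append(result.standard_errors["sigma"])
    if len(sigma_hats) < 2:
        raise RuntimeError(f"only {len(sigma_hats)} of {n_reps} replicate fits converged")

    sigma_hats_arr = np.asarray(sigma_hats)
    z = (sigma_hats_arr - sigma_expected) / np.asarray(ses)
    return ReplicateStudyResult(
        sigma_expected=sigma_expected,
        sigma_hats=tuple(sigma_hats),
        ses=tuple(ses),
        z_scores=tuple(z.tolist()),
        mean_deviation=float(sigma_hats_arr.mean() - sigma_expected),
        se_mean_deviation=float(sigma_hats_arr.std(ddof=1) / math.sqrt(len(sigma_hats))),
        n_failed=n_failed,
    )
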