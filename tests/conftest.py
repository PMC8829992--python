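"""Shared fixtures: the default dose sweeps, their fits, and the epi replicate runs.

The heavy session-scoped fixtures are computed once and shared between the
property tests and the acceptance tests.  All randomness flows from a single
module-level seed.
"""

from __future__ import annotations

import numpy as np
import pytest

import logndose as ld

SEED = 1729


@pytest.fixture(scope="session")
def sweep03():
    """Default 11-point sweep, sigma1 = 0.3, N = 1e6 per point."""
    return ld.run_sweep(ld.SweepConfig(sigma1=0.3, seed=SEED))


@pytest.fixture(scope="session")
def sweep04():
    """Same grid with sigma1 = 0.4."""
    return ld.run_sweep(ld.SweepConfig(sigma1=0.4, seed=SEED + 1))


@pytest.fixture(scope="session")
def logn_fit03(sweep03):
    return ld.fit_cumulative_lognormal(sweep03)


@pytest.fixture(scope="session")
def logn_fit04(sweep04):
    return ld.fit_cumulative_lognormal(sweep04)


@pytest.fixture(scope="session")
def power_fit03(sweep03):
    return ld.fit_power_law(sweep03)


@pytest.fixture(scope="session")
def power_fit04(sweep04):
    return ld.fit_power_law(sweep04)


@pytest.fixture(scope="session")
def epi_recovery_fits():
    """100 synthetic series at the default truth, each fitted with profile SEs."""
    fits = []
    for child in np.random.SeedSequence(SEED).spawn(100):
        records = ld.generate_epi_series(seed=child)
        fits.append(ld.fit_epi_model(records))
    return fits


@pytest.fixture(scope="session")
def null_p_values():
    """p_cesium over 400 amplitude-0 (no effect) replicates."""
    ps = []
    for child in np.random.SeedSequence(SEED + 7).spawn(400):
        records = ld.generate_epi_series(truth=ld.EpiTruth(amplitude=0.0), seed=child)
        ps.append(ld.fit_epi_model(records, compute_se=False).p_cesium)
    return np.asarray(ps)
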