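"""Shared fixtures: the standard grid/basis configuration and a reference
synthetic cohort (scenario S1, n = 20,000, seed 20250901) that several
modules validate against.  The cohort is generated once per session."""

import numpy as np
import pytest

import lexis2d as lx

S1_SEED = 20250901
S1_N = 20_000


@pytest.fixture(scope="session")
def grid():
    return lx.build_grid((50.0, 100.0), (0.0, 10.5), 1.0, 0.5)


@pytest.fixture(scope="session")
def spec(grid):
    return lx.TensorSmoothSpec.for_grid(grid)


@pytest.fixture(scope="session")
def s1_scenario():
    sc = lx.default_scenarios()["S1"]
    sc.n = S1_N
    return sc


@pytest.fixture(scope="session")
def s1_cohort(s1_scenario):
    return lx.simulate_cohort(s1_scenario, seed=S1_SEED)


@pytest.fixture(scope="session")
def s1_binned(s1_cohort, grid):
    return lx.bin_individuals(s1_cohort.records, grid)


@pytest.fixture(scope="session")
def s1_fits(s1_binned, spec):
    """BIC-selected fits for both causes on the reference cohort."""
    return lx.fit_competing_risks(s1_binned, spec, criterion="bic")


@pytest.fixture(scope="session")
def small_problem():
    """A tiny rich problem (6x5 grid, 4x3 bases) for dense-oracle checks."""
    rng = np.random.default_rng(7)
    grid = lx.build_grid((0.0, 6.0), (0.0, 5.0), 1.0, 1.0)
    spec = lx.TensorSmoothSpec.for_grid(grid, nseg_u=3, nseg_s=2, degree=1)
    R = rng.uniform(5.0, 50.0, size=(6, 5))
    lam = 0.2 * np.exp(0.3 * np.sin(grid.u_mid)[:, None]
                       + 0.2 * np.cos(grid.s_mid)[None, :])
    Y = rng.poisson(R * lam).astype(float)
    return grid, spec, Y, R
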