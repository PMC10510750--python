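"""Shared fixtures: the exemplar network, synthetic datasets and fits.

Expensive objects (fits) are session-scoped; all randomness is seeded so
the suite is reproducible run to run.
"""

import numpy as np
import pytest

from emuflux.estimate import make_fit_problem, solve, solve_inst
from emuflux.fixtures import generate_synthetic_dataset, toynet1


@pytest.fixture(scope="session")
def toyspec():
    return toynet1()


@pytest.fixture(scope="session")
def toynet(toyspec):
    return toyspec.network


@pytest.fixture(scope="session")
def toystrategy(toyspec):
    return toyspec.strategy


@pytest.fixture(scope="session")
def ss_dataset_clean(toyspec):
    return generate_synthetic_dataset(toyspec, noise_molpct=0.0, seed=7,
                                      mode="ss")


@pytest.fixture(scope="session")
def ss_problem_clean(toyspec, ss_dataset_clean):
    ds = ss_dataset_clean
    return make_fit_problem(toyspec.network, ds.mdv_measurements,
                            ds.flux_measurements, toyspec.strategy, mode="ss",
                            net_flux_bounds=toyspec.fit_net_flux_bounds())


@pytest.fixture(scope="session")
def ss_fit_clean(ss_problem_clean):
    return solve(ss_problem_clean, n_starts=3, seed=3)


@pytest.fixture(scope="session")
def ss_dataset_noisy(toyspec):
    return generate_synthetic_dataset(toyspec, noise_molpct=1.0, seed=21,
                                      mode="ss")


@pytest.fixture(scope="session")
def ss_fit_noisy(toyspec, ss_dataset_noisy):
    ds = ss_dataset_noisy
    prob = make_fit_problem(toyspec.network, ds.mdv_measurements,
                            ds.flux_measurements, toyspec.strategy, mode="ss",
                            net_flux_bounds=toyspec.fit_net_flux_bounds())
    return solve(prob, n_starts=4, seed=2)


@pytest.fixture(scope="session")
def inst_dataset_clean(toyspec):
    return generate_synthetic_dataset(toyspec, noise_molpct=0.0, seed=5,
                                      mode="inst")


@pytest.fixture(scope="session")
def inst_fit_clean(toyspec, inst_dataset_clean):
    ds = inst_dataset_clean
    prob = make_fit_problem(toyspec.network, ds.mdv_measurements,
                            ds.flux_measurements, ds.strategy, mode="inst",
                            net_flux_bounds=toyspec.fit_net_flux_bounds(),
                            pools_init={m: 1.0 for m in ds.true_pools})
    return solve_inst(prob, n_starts=2, seed=11, max_iter=300)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
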