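import numpy as np
import pytest

import netspread as ns


@pytest.fixture(scope="session")
def conn20():
    """Small random connectome shared across read-only tests."""
    return ns.synth_connectome(20, 0.3, rng_seed=11)


@pytest.fixture(scope="session")
def conn40():
    return ns.synth_connectome(40, 0.25, rng_seed=5)


@pytest.fixture(scope="session")
def planted_study(conn40):
    """Noisy pathology generated from known parameters with planted offsets."""
    truth = ns.default_truth(conn40, delta_sd=0.15, rng_seed=6)
    pathology = ns.synth_pathology(conn40, truth, n_mice=5, noise_sd=0.1, rng_seed=7)
    summary = ns.summarize_pathology(pathology, conn40)
    return truth, pathology, summary


@pytest.fixture(scope="session")
def noiseless_study(conn40):
    truth = ns.default_truth(conn40, rng_seed=21)
    pathology = ns.synth_pathology(conn40, truth, n_mice=1, noise_sd=0.0, rng_seed=22)
    summary = ns.summarize_pathology(pathology, conn40)
    return truth, summary


@pytest.fixture(scope="session")
def noiseless_fit(conn40, noiseless_study):
    truth, summary = noiseless_study
    return ns.fit_model(
        summary, conn40, truth.seed_region, config=ns.FitConfig(grid_size=12)
    )
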