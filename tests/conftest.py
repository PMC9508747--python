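import numpy as np
import pytest

import mtspread as mt


@pytest.fixture(scope="session")
def study():
    """One default-scale synthetic study shared across read-only tests."""
    return mt.synthesize_study(seed=11)


@pytest.fixture(scope="session")
def fits(study):
    return mt.fit_tau_gmm(study.baseline, seed=11)


@pytest.fixture(scope="session")
def scores(study, fits):
    return mt.compute_tau_scores(study.baseline, fits)


@pytest.fixture()
def small_atlas():
    return mt.generate_atlas(4, (20, 20, 20), seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
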