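import warnings

import numpy as np
import pytest

import mediadoe as md

warnings.filterwarnings("ignore", category=RuntimeWarning, module="mediadoe")


@pytest.fixture(scope="session")
def space9():
    return md.default_custom_space()


@pytest.fixture(scope="session")
def space21():
    return md.default_screening_space()


@pytest.fixture(scope="session")
def custom_design(space9):
    # fewer exchange starts than the library default: the fixture needs a
    # valid full-rank design, not the global optimum
    return md.make_custom_design(space9, 56, 7, seed=11, n_starts=5)


@pytest.fixture(scope="session")
def screening_design(space21):
    return md.make_screening_design(space21, 8, 8, seed=11)


@pytest.fixture(scope="session")
def truth9(space9):
    return md.default_truth(space9, seed=42)


@pytest.fixture(scope="session")
def responses9(custom_design, truth9):
    return md.simulate_response(custom_design, truth9, n_bio=3, n_tech=2)


@pytest.fixture(scope="session")
def Xy9(custom_design, responses9):
    X, y, groups = md.build_predictor_matrix(
        custom_design, responses9, include_interactions="all"
    )
    return X, y, groups


@pytest.fixture(scope="session")
def run_means9(Xy9, responses9):
    X, y, groups = Xy9
    run_means = responses9.groupby("run_id", sort=True)["delta_od600"].mean()
    Xr = X.copy()
    Xr["run_id"] = groups
    X_run = Xr.groupby("run_id", sort=True).first()
    return X_run, run_means.to_numpy()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2026)
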