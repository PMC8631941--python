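"""Shared fixtures: the packaged ground truth and derived objects."""

import numpy as np
import pytest

import statescape as sc


@pytest.fixture(scope="session")
def truth():
    return sc.make_ground_truth(7, "three_basin", seed=1)


@pytest.fixture(scope="session")
def landscape_and_map(truth):
    return sc.analyze_landscape(truth.params, strict_three=True)


@pytest.fixture(scope="session")
def big_series(truth):
    """1e5 i.i.d. samples from the ground-truth Boltzmann distribution."""
    return sc.sample_binary_series(truth, 100_000, persistence=0.0, seed=1)


@pytest.fixture(scope="session")
def fitted(big_series):
    """Pairwise MEM fitted to the big synthetic series."""
    return sc.fit_pairwise_mem(big_series, tol=1e-4)


def ferromagnet2(j=1.0, h=(0.0, 0.0)):
    """Two-spin toy model used across the landscape tests."""
    return sc.MEMParams(h=np.array(h, float), J=np.array([[0.0, j], [j, 0.0]]))
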