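import io

import numpy as np
import pytest

import wellmix as wm


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_csv(tmp_path):
    """8-row field table: 2 wells x 4 fields, one condition."""
    text = "condition,well_id,field_index,cell_count,prop_S,prop_G2,prop_M,prop_apoptotic\n"
    rows = []
    for w in ("A1", "A2"):
        for k in range(4):
            rows.append(f"GL2,{w},{k},{100 + 10 * k},0.2,0.3,0.05,0.04")
    path = tmp_path / "fields.csv"
    path.write_text(text + "\n".join(rows) + "\n")
    return path


@pytest.fixture(scope="session")
def neg_small():
    """Small negative-control-like dataset shared across read-only tests."""
    data, scen, labels = wm.make_scenario("negative_like", seed=42, n_wells=60)
    return data, scen, labels


@pytest.fixture(scope="session")
def toy_copula_params():
    R = np.array([[1.0, 0.5], [0.5, 1.0]])
    marginals = (
        wm.MarginalParams("gamma", 2.0, 3.0),
        wm.MarginalParams("beta", 2.0, 5.0),
    )
    return wm.CopulaClassParams(R, marginals)


def two_class_gaussian_truth():
    """Well-separated 2-class hierarchical Gaussian truth inside descriptor supports."""
    c1 = wm.GaussianClassParams(
        np.array([500.0, 0.2, 0.3, 0.05, 0.05]), np.diag([50.0, 0.03, 0.03, 0.01, 0.01]) ** 2
    )
    c2 = wm.GaussianClassParams(
        np.array([1500.0, 0.4, 0.1, 0.15, 0.10]), np.diag([100.0, 0.03, 0.03, 0.02, 0.02]) ** 2
    )
    return wm.MixtureModel([0.4, 0.6], [c1, c2], "gaussian_full", wm.DEFAULT_DESCRIPTORS)
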