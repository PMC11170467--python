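"""Shared fixtures: one planted-effect cohort and its downstream products,
computed once per session, plus a small helper for noise-padded feature
benches."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import eegconn as e
from eegconn.pipeline import default_couplings


@pytest.fixture(scope="session")
def planted_cohort():
    """Default synthetic cohort with the standard planted effects."""
    cfg = e.RunConfig(couplings=default_couplings(), seed=3)
    subjects, truth = e.generate_cohort(cfg.cohort_spec())
    return subjects, truth


@pytest.fixture(scope="session")
def planted_tensor(planted_cohort):
    subjects, _ = planted_cohort
    return e.connectivity_tensor(subjects)


@pytest.fixture(scope="session")
def planted_selection(planted_tensor):
    return e.select_edges(planted_tensor, n_perm=5000, seed=3)


@pytest.fixture(scope="session")
def coherence_features(planted_tensor, planted_selection):
    survivors = [r for r in planted_selection if r.passes_fdr]
    return e.assemble_features(planted_tensor, survivors,
                               "complementary_frequency", family="Coh")


def make_feature_bench(seed: int, n_per: int = 40, n_sig: int = 5,
                       n_noise: int = 25, effect: float = 1.3):
    """Feature matrix with a few informative columns of tapering effect size
    followed by pure-noise columns; returns (FeatureMatrix, ranking)."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per
    y = np.r_[np.zeros(n_per, int), np.ones(n_per, int)]
    X = rng.standard_normal((n, n_sig + n_noise))
    for j in range(n_sig):
        X[y == 1, j] += effect * (1 - 0.12 * j)
    names = ([f"sig{j}" for j in range(n_sig)]
             + [f"noise{j}" for j in range(n_noise)])
    prov = pd.DataFrame(
        {"family": "synthetic", "variant": "value", "band": "broadband",
         "region_a": 0, "region_b": 1, "direction": "hyper"},
        index=range(n_sig + n_noise))
    return e.FeatureMatrix(X, y, names, prov), names
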