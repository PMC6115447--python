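"""Shared fixtures.

The replicated group comparisons used by the acceptance tests are expensive
(hundreds of lasso fits at p = 4000), so they are computed once per session
and shared across the tests that read different columns of the same tables.
"""

from __future__ import annotations

import numpy as np
import pytest

import assl


@pytest.fixture(scope="session")
def toy_binary():
    """Well-conditioned, non-separable 20x2 logistic toy problem."""
    rng = np.random.default_rng(42)
    X = rng.standard_normal((20, 2))
    eta = 0.3 + 1.2 * X[:, 0] - 0.7 * X[:, 1]
    y = (rng.random(20) < 1 / (1 + np.exp(-eta))).astype(int)
    # regenerate until both classes present and not separable in practice
    assert 0 < y.sum() < 20
    return X, y


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic dataset cheap enough for loop-level integration tests."""
    cfg = assl.group_config("A", seed=5, n1=40, n2=80, p=150, n_true=5)
    return assl.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def group_a_experiment():
    """The replicated Group A comparison of all six variants (paired design)."""
    return assl.run_experiment(groups=["A"], replicates=20, master_seed=20260101)


@pytest.fixture(scope="session")
def group_b_autoassl():
    """Group B replicates for the headline-accuracy check (Auto-ASSL-B only)."""
    return assl.run_experiment(
        groups=["B"],
        variants=[assl.Variant.AUTO_ASSL_B],
        replicates=12,
        master_seed=20260101,
    )
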