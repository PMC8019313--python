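"""Shared fixtures.

The trained-network fixtures are session-scoped: each is one desk-scale
training run reused by every test that inspects that model, so the
expensive work happens once per session.
"""

import numpy as np
import pytest

from schemabind import experiments as ex


@pytest.fixture(scope="session")
def limited_unseen_result():
    """LSTM trained on a limited filler pool, tested on a disjoint pool."""
    return ex.run_limited_unseen_lstm(seed=1)


@pytest.fixture(scope="session")
def violation_result():
    """Fast Weights trained to convergence on the reduced violation design."""
    return ex.run_violation_fastweights(seed=2)


@pytest.fixture(scope="session")
def unlimited_fw():
    """Fast Weights trained in the unlimited-filler regime."""
    return ex.run_unlimited("fastweights", seed=3)


@pytest.fixture(scope="session")
def unlimited_rnn():
    """Plain RNN trained in the unlimited-filler regime (same conditions)."""
    return ex.run_unlimited("rnn", seed=3)


@pytest.fixture(scope="session")
def retention_trials():
    """Five independent correlation-retention trials with Fast Weights."""
    return [ex.run_retention_fastweights(seed=100 + k) for k in range(5)]
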