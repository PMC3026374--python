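import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")

from nsdbn.preprocess import DiscreteMatrix, ExpressionMatrix
from nsdbn.regulators import CandidateRegulators
from nsdbn.scoring import Model, PriorConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_expression():
    """3 genes x 6 time points, no missing values, means near 1."""
    values = np.array([
        [1.0, 1.3, 0.9, 1.0, 0.8, 1.0],
        [0.9, 1.0, 1.4, 1.0, 1.0, 0.7],
        [1.0, 1.0, 1.0, 1.2, 0.9, 0.9],
    ])
    return ExpressionMatrix(values, ["A", "B", "C"])


def make_toy_model(T=10, seed=1, tau_max=2, m_max=3, lambda_m=0.5, lambda_s=1.0,
                   lag_probs=(0.6, 0.4), self_loops=False, flat=False):
    """2-gene discrete toy with mutual candidate regulators."""
    r = np.random.default_rng(seed)
    levels = r.integers(0, 3, size=(2, T))
    disc = DiscreteMatrix(levels, ["A", "B"], levels.mean(axis=1))
    cand = CandidateRegulators({"A": {"B"}, "B": {"A"}},
                               np.asarray(lag_probs, dtype=float), len(lag_probs))
    priors = PriorConfig(lambda_m=lambda_m, lambda_s=lambda_s, alpha=1.0,
                         tau_max=tau_max, m_max=m_max, self_loops=self_loops)
    return Model(disc, cand, priors, flat_likelihood=flat)


@pytest.fixture
def toy_model():
    return make_toy_model()
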