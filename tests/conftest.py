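import numpy as np
import pytest

from fdp.expression_dynamics import ExpressionProfile
from fdp.synthetic import FixtureSpec, generate


@pytest.fixture(scope="session")
def small_fixture():
    """A 60-gene planted dataset reused across modules."""
    return generate(FixtureSpec(n_genes=60, fraction_essential=0.2, seed=3))


@pytest.fixture(scope="session")
def small_profiles(small_fixture):
    return {
        g: ExpressionProfile(g, row.to_numpy())
        for g, row in small_fixture.expression.iterrows()
    }


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def random_row_stochastic(rng, n):
    """A dense row-stochastic matrix for walk/entropy tests."""
    H = rng.uniform(0.0, 1.0, (n, n))
    np.fill_diagonal(H, 0.0)
    return H / H.sum(axis=1, keepdims=True)
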