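import numpy as np
import pytest

import seamtube as st


@pytest.fixture(scope="session")
def cone():
    """Textbook isotropic cone: E_pm = +-r, gap = 2r, seam at the origin."""
    return st.isotropic_cone_model()


@pytest.fixture(scope="session")
def anis_cone():
    """Linear cone with slopes 2 (tuning) and 1 (coupling)."""
    return st.anisotropic_cone_model(2.0, 1.0)


@pytest.fixture(scope="session")
def fixture1():
    """Conical fixture seed=1, N=3: model plus its closed-form spec."""
    return st.conical_fixture(1, 3)


@pytest.fixture(scope="session")
def avoided():
    """Avoided crossing with minimum gap 0.3 (c0 = 0.15), N = 3."""
    return st.avoided_crossing_fixture(3, 3, 0.15)


@pytest.fixture(scope="session")
def linear_fix():
    """Glancing intersection (V12 = 0), N = 3."""
    return st.linear_intersection_fixture(5, 3)


def fixture_suite(n_seeds=10):
    """Conical fixtures over seeds 1..n_seeds with N cycling 3..6."""
    out = []
    for seed in range(1, n_seeds + 1):
        n = 3 + (seed - 1) % 4
        out.append((seed, *st.conical_fixture(seed, n)))
    return out


def start_point(spec, seed):
    """Deterministic off-seam starting geometry near a fixture's MECI."""
    rng = np.random.default_rng(seed)
    return spec.meci_point + rng.uniform(-1.0, 1.0, spec.dimension)
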