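import numpy as np
import pytest
from scipy.stats import norm

from mmpibn.gbn import Dag, GaussianNetwork, LinearGaussianCpd
from mmpibn.simulate import StudyConfig, make_two_group_study, mmpi2_preset


@pytest.fixture(scope="session")
def preset_pair():
    return mmpi2_preset()


@pytest.fixture(scope="session")
def small_cohort():
    """200-per-group synthetic cohort for fast end-to-end tests."""
    return make_two_group_study(StudyConfig(n_per_group=200, seed=11))


@pytest.fixture
def two_node_net():
    """X ~ N(0,1), Y = 2X + 1 + N(0,1)."""
    dag = Dag(("X", "Y"), frozenset({("X", "Y")}))
    return GaussianNetwork(dag, {
        "X": LinearGaussianCpd("X", (), (), 0.0, 1.0),
        "Y": LinearGaussianCpd("Y", ("X",), (2.0,), 1.0, 1.0),
    })


def z_threshold(n_comparisons: int) -> float:
    """Per-comparison |z| bound with the familywise error of one 3-sigma test.

    Monte-Carlo moment checks compare many entries at once; a flat 3-SE
    bound per entry would reject correct code with high probability.  This
    Sidak adjustment keeps the overall false-alarm rate at the two-sided
    3-sigma level (0.27%).
    """
    alpha = 2 * norm.sf(3.0)
    per = 1 - (1 - alpha) ** (1 / n_comparisons)
    return float(norm.isf(per / 2))


def random_network(p: int, seed: int, expected_arcs: float | None = None):
    """Small helper shared across tests: random network over p nodes."""
    from mmpibn.simulate import make_random_dag, make_random_network

    rng = np.random.default_rng(seed)
    if expected_arcs is None:
        expected_arcs = p
    dag = make_random_dag(p, expected_arcs, rng)
    return make_random_network(dag, seed=rng)
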