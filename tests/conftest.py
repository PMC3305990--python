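import numpy as np
import pytest
from hypothesis import settings

from crnreal.examples import (
    POSITIVE_FEEDBACK_RATES,
    positive_feedback_network,
    random_rates,
    repressilator_network,
    yeast_switch_network,
)
from crnreal.realize import RealizationProblem

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")

YEAST_SEEDS = (11, 12)
REPRESSILATOR_SEEDS = (21, 22)


@pytest.fixture(scope="session")
def pf_net():
    return positive_feedback_network()


@pytest.fixture(scope="session")
def pf_problem(pf_net):
    return RealizationProblem.from_network(pf_net)


@pytest.fixture(scope="session")
def pf_dense(pf_problem):
    return pf_problem.dense()


@pytest.fixture(scope="session")
def pf_core(pf_problem, pf_dense):
    return pf_problem.core(pf_dense)


@pytest.fixture(scope="session")
def pf_minimal_supports(pf_problem, pf_dense):
    return pf_problem.enumerate_sparse(16, pf_dense)


@pytest.fixture(scope="session")
def yeast_results():
    """Dense/core/sparse-enumeration bundle of the yeast switch at two seeds."""
    out = {}
    for seed in YEAST_SEEDS:
        net = yeast_switch_network(random_rates(seed))
        prob = RealizationProblem.from_network(net)
        dense = prob.dense()
        out[seed] = {
            "net": net,
            "prob": prob,
            "dense": dense,
            "core": prob.core(dense),
            "supports": prob.enumerate_sparse(8, dense),
        }
    return out


@pytest.fixture(scope="session")
def repressilator_results():
    """Dense/core/sparse bundle of the 5-gene repressilator at two seeds."""
    out = {}
    for seed in REPRESSILATOR_SEEDS:
        net = repressilator_network(random_rates(seed))
        prob = RealizationProblem.from_network(net)
        dense = prob.dense()
        out[seed] = {
            "net": net,
            "prob": prob,
            "dense": dense,
            "core": prob.core(dense),
            "sparse": prob.sparse(dense),
        }
    return out


def small_test_networks():
    """Deterministic small CRNs (<= 4 complexes) for brute-force cross-checks."""
    from crnreal.model import ComplexMatrix, KirchhoffMatrix, ReactionNetwork

    nets = []
    rng = np.random.default_rng(1234)
    # hand-picked: a reversible pair plus a catalytic triangle
    nets.append(
        ReactionNetwork.from_reactions(
            ["A", "B"],
            [{"A": 1}, {"B": 1}, {"A": 1, "B": 1}],
            {(0, 1): 1.0, (1, 0): 2.0, (2, 0): 0.5},
        )
    )
    nets.append(
        ReactionNetwork.from_reactions(
            ["A", "B"],
            [{"A": 2}, {"A": 1, "B": 1}, {"B": 2}],
            {(0, 1): 1.0, (1, 2): 1.0, (2, 0): 1.0},
        )
    )
    # random small networks
    attempts = 0
    while len(nets) < 8 and attempts < 200:
        attempts += 1
        n = int(rng.integers(2, 4))
        m = int(rng.integers(3, 5))
        Y = rng.integers(0, 3, size=(n, m))
        if len({tuple(c) for c in Y.T}) != m:
            continue
        k = int(rng.integers(2, 5))
        pairs = [(a, b) for a in range(m) for b in range(m) if a != b]
        idx = rng.choice(len(pairs), size=min(k, len(pairs)), replace=False)
        rates = {pairs[i]: float(rng.uniform(0.5, 3.0)) for i in idx}
        try:
            cm = ComplexMatrix([f"S{i}" for i in range(n)], Y)
            nets.append(
                ReactionNetwork(cm, KirchhoffMatrix.from_reactions(m, rates))
            )
        except Exception:
            continue
    return nets
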