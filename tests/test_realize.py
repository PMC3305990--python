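"""Tests for dense/sparse/core realization computations.

The brute-force oracle here deliberately uses the *full-matrix* LP
formulation (all off-diagonal and diagonal entries as variables, explicit
column-sum rows, solved directly with scipy) so that the package's
column-decomposed implementation is cross-checked against an independent
route, and subset enumeration gives sparse cardinality and core sets by
exhaustion on small networks.
"""

import itertools

import numpy as np
import pytest
import scipy.optimize as sopt

from crnreal.model import ReactionNetwork, ReactionSupport, invariant_matrix
from crnreal.realize import (
    ConstraintSet,
    NotRealizableError,
    RealizationProblem,
    dense_realization,
    edge_max_rate,
    is_structure_unique,
    sparse_realization,
)
from crnreal.examples import positive_feedback_network

from conftest import small_test_networks

ZTOL = 1e-7


# -- independent full-matrix LP oracle --------------------------------------


def _full_lp(Y, M, allowed=None, forced_zero=(), maximize_edge=None, u=1e6):
    """Solve the realization LP in the full-matrix formulation with scipy."""
    n, m = Y.shape
    offs = [(i, j) for j in range(m) for i in range(m) if i != j]  # A[i, j]
    col = {e: k for k, e in enumerate(offs)}
    nv = len(offs) + m  # off-diagonals then diagonal
    rows, rhs = [], []
    for r in range(n):
        for j in range(m):
            row = np.zeros(nv)
            for i in range(m):
                if i == j:
                    row[len(offs) + j] += Y[r, j]
                else:
                    row[col[(i, j)]] += Y[r, i]
            rows.append(row)
            rhs.append(M[r, j])
    for j in range(m):  # column conservation
        row = np.zeros(nv)
        for i in range(m):
            row[col[(i, j)] if i != j else len(offs) + j] = 1.0
        rows.append(row)
        rhs.append(0.0)
    bounds = []
    for (i, j) in offs:
        edge = (j, i)  # (source, target)
        shut = (allowed is not None and edge not in allowed) or edge in forced_zero
        bounds.append((0.0, 0.0) if shut else (0.0, u))
    bounds += [(None, 0.0)] * m
    c = np.zeros(nv)
    if maximize_edge is not None:
        src, tgt = maximize_edge
        c[col[(tgt, src)]] = -1.0
    res = sopt.linprog(c, A_eq=np.array(rows), b_eq=np.array(rhs),
                       bounds=bounds, method="highs")
    return res


def oracle_dense_support(net):
    Y, M = net.complexes.Y, invariant_matrix(net)
    m = Y.shape[1]
    edges = []
    for src in range(m):
        for tgt in range(m):
            if src == tgt:
                continue
            res = _full_lp(Y, M, maximize_edge=(src, tgt))
            assert res.status == 0
            if -res.fun > ZTOL:
                edges.append((src, tgt))
    return ReactionSupport(edges, m)


def oracle_subset_scan(net, dense_support):
    """Minimal feasible subset size and the intersection of feasible subsets."""
    Y, M = net.complexes.Y, invariant_matrix(net)
    edges = sorted(dense_support.edges)
    feasible = []
    for r in range(len(edges) + 1):
        for subset in itertools.combinations(edges, r):
            res = _full_lp(Y, M, allowed=ReactionSupport(subset, Y.shape[1]))
            if res.status == 0:
                feasible.append(frozenset(subset))
    min_card = min(len(s) for s in feasible)
    core = frozenset.intersection(*feasible)
    return min_card, core


# -- positive feedback motif ------------------------------------------------


class TestPositiveFeedback:
    def test_dense_support_counts(self, pf_dense):
        assert len(pf_dense.support) == 12

    def test_original_edges_have_positive_maxima(self, pf_net, pf_dense):
        for edge in pf_net.support():
            assert pf_dense.edge_max_values[tuple(edge)] > ZTOL

    def test_edge_absent_from_dense_has_zero_maximum(self, pf_problem, pf_dense):
        m = pf_problem.m
        absent = next(
            (q, p)
            for q in range(m)
            for p in range(m)
            if q != p and (q, p) not in pf_dense.support
        )
        assert pf_problem.edge_max(absent) <= ZTOL

    def test_core_partition(self, pf_core):
        assert len(pf_core.core) == 8
        assert len(pf_core.non_core) == 4
        assert not (pf_core.core.edges & pf_core.non_core.edges)

    def test_sparse_cardinality_is_nine(self, pf_problem, pf_dense):
        assert pf_problem.sparse(pf_dense).cardinality == 9

    def test_three_minimal_supports_including_original(
        self, pf_net, pf_minimal_supports
    ):
        assert len(pf_minimal_supports) == 3
        assert all(len(s) == 9 for s in pf_minimal_supports)
        assert pf_net.support() in pf_minimal_supports

    def test_not_structurally_unique(self, pf_net):
        unique, witness = is_structure_unique(
            pf_net.complexes, invariant_matrix(pf_net)
        )
        assert not unique
        assert len(witness.dense_support) == 12
        assert len(witness.sparse_support) == 9

    def test_fully_constrained_reduces_to_original(self, pf_net):
        m = pf_net.n_complexes
        orig = pf_net.support()
        K = ConstraintSet(
            [(a, b) for a in range(m) for b in range(m)
             if a != b and (a, b) not in orig],
            m,
        )
        prob = RealizationProblem.from_network(pf_net, K)
        dense = prob.dense()
        assert dense.support == orig
        ok, witness = prob.unique()
        assert ok

    def test_core_contained_in_every_minimal_support(
        self, pf_core, pf_minimal_supports, pf_net, pf_dense
    ):
        for sup in pf_minimal_supports + [pf_net.support(), pf_dense.support]:
            assert pf_core.core.issubset(sup)

    def test_epsilon_positive_exactly_on_dense_support(self, pf_dense, pf_problem):
        for edge, eps in pf_dense.epsilon.items():
            if edge in pf_dense.support:
                assert eps > 0
            else:
                assert eps <= ZTOL

    def test_dense_realization_matches_support_and_dynamics(self, pf_net, pf_dense):
        M = invariant_matrix(pf_net)
        R = pf_dense.realization
        assert R.support(ZTOL) == pf_dense.support
        resid = np.abs(invariant_matrix(R) - M).max()
        assert resid <= 1e-6 * max(1.0, np.abs(M).max())


class TestInvariantsAndOracles:
    @pytest.mark.parametrize("idx", range(8))
    def test_small_network_oracle_agreement(self, idx):
        nets = small_test_networks()
        net = nets[idx]
        prob = RealizationProblem.from_network(net)
        dense = prob.dense()
        oracle_support = oracle_dense_support(net)
        assert dense.support == oracle_support
        # P1: the original structure is inside the dense one
        assert net.support().issubset(dense.support)
        if 2 ** len(dense.support) > 2048:
            return
        min_card, core_edges = oracle_subset_scan(net, dense.support)
        assert prob.sparse(dense).cardinality == min_card
        assert prob.core(dense).core.edges == core_edges

    def test_equivalence_residuals(self, pf_net, pf_problem, pf_dense):
        M = invariant_matrix(pf_net)
        scale = max(1.0, np.abs(M).max())
        for result in (pf_dense.realization, pf_problem.sparse(pf_dense).realization):
            assert np.abs(invariant_matrix(result) - M).max() <= 1e-6 * scale
            A = result.kinetics.A
            assert np.abs(A.sum(axis=0)).max() <= 1e-8 * max(1.0, np.abs(A).max())

    def test_dense_support_invariant_under_complex_permutation(self, pf_net, pf_dense):
        rng = np.random.default_rng(2)
        perm = rng.permutation(pf_net.n_complexes)
        from crnreal.model import ComplexMatrix, KirchhoffMatrix

        cm = ComplexMatrix(pf_net.complexes.species, pf_net.complexes.Y[:, perm])
        A = pf_net.kinetics.A[np.ix_(perm, perm)]
        permuted = ReactionNetwork(cm, KirchhoffMatrix(A))
        dense_p = RealizationProblem.from_network(permuted).dense()
        inv = np.argsort(perm)
        mapped = ReactionSupport(
            [(int(perm[a]), int(perm[b])) for a, b in dense_p.support]
        )
        assert mapped == pf_dense.support

    def test_dense_support_insensitive_to_upper_bound(self, pf_net, pf_dense):
        for u in (1e2, 1e4):
            alt = RealizationProblem.from_network(pf_net, u_scale=u).dense()
            assert alt.support == pf_dense.support

    def test_constraint_monotonicity(self, pf_net, pf_core, pf_dense, pf_problem):
        # excluding a non-core reaction can only shrink the dense support and
        # can never lower the minimal cardinality
        edge = sorted(pf_core.non_core.edges)[0]
        constrained = RealizationProblem.from_network(pf_net, [edge])
        dense_c = constrained.dense()
        assert dense_c.support.issubset(pf_dense.support)
        assert edge not in dense_c.support
        assert constrained.sparse(dense_c).cardinality >= pf_problem.sparse(
            pf_dense
        ).cardinality

    def test_determinism(self, pf_net, pf_dense):
        again = RealizationProblem.from_network(pf_net).dense()
        assert again.support == pf_dense.support
        assert again.edge_max_values == pf_dense.edge_max_values


class TestSingleReaction:
    @pytest.fixture()
    def chain(self):
        return ReactionNetwork.from_reactions(
            ["X1", "X2"], [{"X1": 1}, {"X2": 1}], {(0, 1): 1.8}
        )

    def test_edge_max_equals_rate(self, chain):
        val = edge_max_rate(
            chain.complexes, invariant_matrix(chain), None, (0, 1)
        )
        assert val == pytest.approx(1.8)

    def test_scaling_homogeneity(self, chain):
        M = invariant_matrix(chain)
        v1 = edge_max_rate(chain.complexes, M, None, (0, 1))
        v2 = edge_max_rate(chain.complexes, 2.0 * M, None, (0, 1))
        assert v2 == pytest.approx(2.0 * v1)

    def test_sparse_and_core_are_the_reaction(self, chain):
        prob = RealizationProblem.from_network(chain)
        dense = prob.dense()
        sp = prob.sparse(dense)
        assert sp.cardinality == 1
        assert sp.support == chain.support()
        assert prob.core(dense).core == chain.support()

    def test_excluding_the_reaction_is_not_realizable(self, chain):
        prob = RealizationProblem.from_network(chain, [(0, 1)])
        with pytest.raises(NotRealizableError):
            prob.dense()


class TestExtendedComplexSet:
    def test_extended_counts(self):
        net = positive_feedback_network(extended=True)
        prob = RealizationProblem.from_network(net)
        dense = prob.dense()
        report = prob.core(dense)
        assert len(dense.support) == 17
        assert len(report.core) == 5
        assert len(report.non_core) == 12
        assert prob.sparse(dense).cardinality == 9

    def test_extended_minimal_structures_are_few(self):
        # of the hundreds of 9-subsets of the 17 dense reactions that could
        # conceivably work, exhaustive no-good-cut enumeration finds only 3
        net = positive_feedback_network(extended=True)
        prob = RealizationProblem.from_network(net)
        supports = prob.enumerate_sparse(500)
        assert len(supports) == 3
        assert all(len(s) == 9 for s in supports)
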