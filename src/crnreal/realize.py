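"""Dense, sparse, constrained and core realizations of a kinetic vector field.

Given a fixed complex set ``Y`` and the invariant matrix ``M = Y . A_k`` of
some mass-action network, the set of all dynamically equivalent realizations
is the polyhedron of Kirchhoff matrices satisfying ``Y . A_k = M``.  Three
structural objects characterise it:

* the **dense** realization -- the unique maximal unweighted reaction graph;
  every equivalent realization's graph is one of its subgraphs (it is a
  super-structure), so membership of an edge is decided by one LP that
  maximises that edge's rate coefficient;
* **sparse** realizations -- graphs with the minimal number of reactions,
  found by a cardinality MILP (generally non-unique; all minimum-cardinality
  supports can be enumerated with no-good cuts);
* **core** reactions -- edges present in *every* equivalent realization,
  detected by an LP feasibility test with the edge forced to zero.

A *constraint set* forces selected reactions to zero and yields the
constrained variants of all three; a structure is unique under the given
constraints exactly when the dense and sparse supports coincide.

Numerical notes.  The constraints ``Y . A_k = M`` together with column
conservation never couple two columns of ``A_k``, so every program is solved
column-by-column after eliminating the diagonal entry (the column sum fixes
it).  Programs are handed to the solver in raw units -- rate coefficients in
realistic models span many decades within one column, and any single column
scaling pushes the small ones under the solver's feasibility tolerance; the
solver's own equilibration copes with the spread, and empirically returns
exact zeros for absent edges.  An edge therefore counts as present when its
maximal rate exceeds an absolute threshold ``zero_tol`` (default 1e-7, far
above observed solver noise and far below realistic rate coefficients).
Every support claimed by the cardinality MILP is re-verified by a plain LP
feasibility check so that big-M or integrality tolerances can never fake a
smaller realization.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np

from . import optim
from .model import (
    ComplexMatrix,
    CRNError,
    KirchhoffMatrix,
    ReactionNetwork,
    ReactionSupport,
    column_scales,
    invariant_matrix,
)

__all__ = [
    "NotRealizableError",
    "ConstraintSet",
    "DenseResult",
    "SparseResult",
    "CoreReport",
    "RealizationProblem",
    "edge_max_rate",
    "dense_realization",
    "sparse_realization",
    "enumerate_sparse_supports",
    "core_reactions",
    "is_structure_unique",
]

#: absolute threshold above which a rate coefficient counts as present
DEFAULT_ZERO_TOL = 1e-7

#: ratio between the per-column upper bound U and the column scale of M
DEFAULT_U_SCALE = 1e3


class NotRealizableError(Exception):
    """The dynamics admit no realization with the given complex/constraint sets."""


class ConstraintSet:
    """Reactions excluded a priori: ordered complex pairs forced to rate zero."""

    __slots__ = ("excluded",)

    def __init__(self, excluded: Iterable[tuple[int, int]] = (), m: int | None = None):
        pairs = frozenset((int(a), int(b)) for a, b in excluded)
        for a, b in pairs:
            if a == b:
                raise CRNError(f"cannot exclude self-loop ({a}, {b})")
            if a < 0 or b < 0 or (m is not None and (a >= m or b >= m)):
                raise CRNError(f"excluded pair ({a}, {b}) out of range")
        self.excluded = pairs

    def __len__(self) -> int:
        return len(self.excluded)

    def __contains__(self, pair) -> bool:
        return tuple(pair) in self.excluded

    def __iter__(self):
        return iter(sorted(self.excluded))

    def __repr__(self) -> str:
        return f"ConstraintSet({sorted(self.excluded)})"


@dataclass
class DenseResult:
    """Outcome of the dense-realization LP sweep.

    ``edge_max_values`` maps each admissible edge to the maximum of its rate
    coefficient over all constrained realizations; ``epsilon`` holds the
    averaged optimizers used as lower bounds when assembling the returned
    realization, positive exactly on the dense support.
    """

    realization: ReactionNetwork
    support: ReactionSupport
    edge_max_values: dict[tuple[int, int], float]
    epsilon: dict[tuple[int, int], float]


@dataclass
class SparseResult:
    realization: ReactionNetwork
    support: ReactionSupport
    cardinality: int


@dataclass
class CoreReport:
    core: ReactionSupport
    non_core: ReactionSupport

    @property
    def dense_support(self) -> ReactionSupport:
        return self.core.union(self.non_core)


class UniquenessWitness(NamedTuple):
    dense_support: ReactionSupport
    sparse_support: ReactionSupport


def _as_constraints(constraints, m: int) -> ConstraintSet:
    if constraints is None:
        return ConstraintSet((), m)
    if isinstance(constraints, ConstraintSet):
        return ConstraintSet(constraints.excluded, m)
    return ConstraintSet(constraints, m)


class RealizationProblem:
    """All realization computations for one ``(Y, M, constraints)`` triple.

    Solver work is organised per column of ``A_k`` (see module docstring);
    the per-column equality blocks are built once and reused by every sweep.
    """

    def __init__(
        self,
        complexes: ComplexMatrix,
        M: np.ndarray,
        constraints: ConstraintSet | Iterable[tuple[int, int]] | None = None,
        *,
        zero_tol: float = DEFAULT_ZERO_TOL,
        u_scale: float = DEFAULT_U_SCALE,
    ) -> None:
        M = np.asarray(M, dtype=float)
        if M.shape != (complexes.n_species, complexes.n_complexes):
            raise CRNError(
                f"invariant matrix of shape {M.shape} does not match "
                f"{complexes.n_species} species x {complexes.n_complexes} complexes"
            )
        self.complexes = complexes
        self.M = M
        self.m = complexes.n_complexes
        self.constraints = _as_constraints(constraints, self.m)
        self.zero_tol = float(zero_tol)
        self.u_scale = float(u_scale)
        #: per-column rate upper bound U, proportional to the column scale of M
        self.u_bounds = self.u_scale * column_scales(M)
        self._eq_cache: dict[int, tuple[np.ndarray, np.ndarray, list[int]]] = {}

    @classmethod
    def from_network(
        cls, net: ReactionNetwork, constraints=None, **kwargs
    ) -> "RealizationProblem":
        return cls(net.complexes, invariant_matrix(net), constraints, **kwargs)

    # -- column programs ---------------------------------------------------

    def _column_system(self, q: int) -> tuple[np.ndarray, np.ndarray, list[int]]:
        """Equality block of column ``q`` with the diagonal eliminated.

        Variables are the off-diagonal entries ``A[p, q]`` for targets
        ``p != q``; substituting the column-sum identity
        ``A[q, q] = -sum_p A[p, q]`` turns ``Y . A[:, q] = M[:, q]`` into
        ``sum_p (Y[:, p] - Y[:, q]) a_p = M[:, q]``.
        """
        if q not in self._eq_cache:
            Y = self.complexes.Y.astype(float)
            targets = [p for p in range(self.m) if p != q]
            a_eq = Y[:, targets] - Y[:, [q]]
            self._eq_cache[q] = (a_eq, self.M[:, q].copy(), targets)
        return self._eq_cache[q]

    def _column_bounds(
        self,
        q: int,
        targets: list[int],
        zero_edges: Iterable[tuple[int, int]] = (),
        allowed: ReactionSupport | None = None,
    ) -> np.ndarray:
        zero = set(zero_edges)
        bounds = np.zeros((len(targets), 2))
        for idx, p in enumerate(targets):
            closed = (
                (q, p) in self.constraints
                or (q, p) in zero
                or (allowed is not None and (q, p) not in allowed)
            )
            bounds[idx] = (0.0, 0.0) if closed else (0.0, self.u_bounds[q])
        return bounds

    def _column_feasible(
        self,
        q: int,
        zero_edges: Iterable[tuple[int, int]] = (),
        allowed: ReactionSupport | None = None,
    ) -> bool:
        a_eq, b_eq, targets = self._column_system(q)
        lp = optim.LinearProgram(
            c=np.zeros(len(targets)),
            bounds=self._column_bounds(q, targets, zero_edges, allowed),
            a_eq=a_eq,
            b_eq=b_eq,
        )
        return optim.check_feasibility(lp)

    def assert_realizable(self) -> None:
        """Raise :class:`NotRealizableError` unless every column is feasible."""
        for q in range(self.m):
            if not self._column_feasible(q):
                raise NotRealizableError(
                    "dynamics not realizable with the given complex and "
                    f"constraint sets (column {q}: {self.complexes.label(q)})"
                )

    def _verify_support(self, support: ReactionSupport) -> bool:
        """Exact LP check that a realization restricted to ``support`` exists."""
        return all(
            self._column_feasible(q, allowed=support) for q in range(self.m)
        )

    # -- dense sweep -------------------------------------------------------

    def edge_max(self, edge: tuple[int, int]) -> float:
        """Maximal rate coefficient of ``edge`` over all constrained realizations."""
        q, p = int(edge[0]), int(edge[1])
        if q == p:
            raise CRNError("self-loop edges are not reactions")
        if (q, p) in self.constraints:
            raise CRNError(f"edge ({q}, {p}) is excluded by the constraint set")
        a_eq, b_eq, targets = self._column_system(q)
        c = np.zeros(len(targets))
        c[targets.index(p)] = 1.0
        lp = optim.LinearProgram(
            c=c,
            bounds=self._column_bounds(q, targets),
            a_eq=a_eq,
            b_eq=b_eq,
            sense="max",
        )
        res = optim.solve(lp)
        if res.status == "infeasible":
            raise NotRealizableError(
                "dynamics not realizable with the given complex and constraint sets"
            )
        if res.status != "optimal":
            raise RuntimeError(f"edge LP failed: {res.status} {res.message}")
        return float(res.objective_value)

    def dense(self) -> DenseResult:
        """LP sweep over all admissible ordered complex pairs.

        For each pair the edge's rate is maximised; the edge belongs to the
        dense support iff the maximum is positive (above the zero
        threshold).  The per-column average of the optimizers -- a feasible
        realization by convexity, positive exactly on the dense support --
        provides the lower bounds for the final feasibility solve that
        assembles the returned realization.
        """
        m = self.m
        A = np.zeros((m, m))
        edge_max: dict[tuple[int, int], float] = {}
        epsilon: dict[tuple[int, int], float] = {}
        support_edges: set[tuple[int, int]] = set()
        for q in range(m):
            a_eq, b_eq, targets = self._column_system(q)
            bounds = self._column_bounds(q, targets)
            free = [
                idx for idx, p in enumerate(targets)
                if (q, p) not in self.constraints
            ]
            if not free:
                # every reaction out of this complex is excluded: the column
                # must vanish identically for the dynamics to be realizable
                if np.abs(b_eq).max(initial=0.0) > self.zero_tol:
                    raise NotRealizableError(
                        f"column {q} ({self.complexes.label(q)}) is fully "
                        "constrained but its dynamics are nonzero"
                    )
                continue
            sols = []
            for idx in free:
                c = np.zeros(len(targets))
                c[idx] = 1.0
                res = optim.solve(
                    optim.LinearProgram(
                        c=c, bounds=bounds, a_eq=a_eq, b_eq=b_eq, sense="max"
                    )
                )
                if res.status == "infeasible":
                    raise NotRealizableError(
                        "dynamics not realizable with the given complex and "
                        "constraint sets"
                    )
                if res.status != "optimal":
                    raise RuntimeError(
                        f"dense-sweep LP failed: {res.status} {res.message}"
                    )
                p = targets[idx]
                edge_max[(q, p)] = float(res.objective_value)
                sols.append(np.maximum(res.values, 0.0))
                if res.objective_value > self.zero_tol:
                    support_edges.add((q, p))
            eps_col = np.mean(sols, axis=0)
            for idx, p in enumerate(targets):
                epsilon[(q, p)] = float(eps_col[idx])
            # final assembly for this column: feasibility with positive lower
            # bounds on the dense edges (capped per the averaging guarantee so
            # they can never make the program infeasible)
            lb = bounds.copy()
            for idx, p in enumerate(targets):
                if (q, p) in support_edges:
                    lb[idx, 0] = min(eps_col[idx], 10.0 * self.zero_tol)
            res = optim.solve(
                optim.LinearProgram(
                    c=np.zeros(len(targets)), bounds=lb, a_eq=a_eq, b_eq=b_eq
                )
            )
            col = eps_col if res.status != "optimal" else np.maximum(res.values, 0.0)
            for idx, p in enumerate(targets):
                if (q, p) in support_edges:
                    A[p, q] = col[idx]
        support = ReactionSupport(support_edges, m)
        A -= np.diag(A.sum(axis=0))
        realization = ReactionNetwork(self.complexes, KirchhoffMatrix(A))
        return DenseResult(realization, support, edge_max, epsilon)

    # -- core reactions ----------------------------------------------------

    def core(self, dense: DenseResult | None = None) -> CoreReport:
        """Partition the dense support into core and non-core reactions.

        An edge is core iff forcing its rate to zero makes the (column)
        realization problem infeasible -- i.e. the reaction appears in every
        dynamically equivalent constrained realization.
        """
        dense = dense or self.dense()
        core_edges, non_core = [], []
        for q, p in dense.support:
            if self._column_feasible(q, zero_edges=[(q, p)]):
                non_core.append((q, p))
            else:
                core_edges.append((q, p))
        return CoreReport(
            ReactionSupport(core_edges, self.m), ReactionSupport(non_core, self.m)
        )

    # -- sparse MILP -------------------------------------------------------

    def _sparse_milp(
        self,
        dense: DenseResult,
        extra_cuts: list[list[int]] | None = None,
        total_cardinality: int | None = None,
    ) -> optim.SolveResult:
        """Cardinality MILP restricted to the dense support.

        Variables: one rate and one binary indicator per dense edge (the
        super-structure property makes other edges unusable).  The rows
        ``a_e <= U_e . delta_e`` link them, with ``U_e`` the edge's known
        maximal rate -- the tightest valid big-M.  Optional no-good cuts
        ``sum_{e in S} delta_e <= |S| - 1`` and a fixed total cardinality
        support enumeration of alternative minimal structures.
        """
        edges = sorted(dense.support.edges)
        idx = {e: i for i, e in enumerate(edges)}
        ne = len(edges)
        nv = 2 * ne  # rates then indicators
        u_edge = np.array([dense.edge_max_values[e] for e in edges])
        rows_eq, rhs_eq = [], []
        for q in range(self.m):
            a_eq, b_eq, targets = self._column_system(q)
            block = np.zeros((a_eq.shape[0], nv))
            for i, p in enumerate(targets):
                if (q, p) in idx:
                    block[:, idx[(q, p)]] = a_eq[:, i]
            rows_eq.append(block)
            rhs_eq.append(b_eq)
        a_eq = np.vstack(rows_eq)
        b_eq = np.concatenate(rhs_eq)
        rows_ub = np.hstack([np.eye(ne), -np.diag(u_edge)])
        rhs_ub = np.zeros(ne)
        if extra_cuts:
            for members in extra_cuts:
                row = np.zeros(nv)
                row[[ne + j for j in members]] = 1.0
                rows_ub = np.vstack([rows_ub, row])
                rhs_ub = np.append(rhs_ub, float(len(members) - 1))
        if total_cardinality is not None:
            row = np.zeros(nv)
            row[ne:] = 1.0
            a_eq = np.vstack([a_eq, row])
            b_eq = np.append(b_eq, float(total_cardinality))
        bounds = np.vstack(
            [np.column_stack([np.zeros(ne), u_edge]), np.tile([0.0, 1.0], (ne, 1))]
        )
        c = np.concatenate([np.zeros(ne), np.ones(ne)])
        integrality = np.concatenate([np.zeros(ne), np.ones(ne)])
        return optim.solve(
            optim.LinearProgram(
                c=c,
                bounds=bounds,
                a_eq=a_eq,
                b_eq=b_eq,
                a_ub=rows_ub,
                b_ub=rhs_ub,
                integrality=integrality,
            )
        )

    def _milp_support(
        self, res: optim.SolveResult, dense: DenseResult
    ) -> ReactionSupport:
        edges = sorted(dense.support.edges)
        ne = len(edges)
        chosen = [e for i, e in enumerate(edges) if res.values[ne + i] > 0.5]
        return ReactionSupport(chosen, self.m)

    def _realize_on_support(self, support: ReactionSupport) -> ReactionNetwork:
        """A realization restricted exactly to ``support`` (LP per column)."""
        A = np.zeros((self.m, self.m))
        for q in range(self.m):
            a_eq, b_eq, targets = self._column_system(q)
            lp = optim.LinearProgram(
                c=np.zeros(len(targets)),
                bounds=self._column_bounds(q, targets, allowed=support),
                a_eq=a_eq,
                b_eq=b_eq,
            )
            res = optim.solve(lp)
            if res.status != "optimal":
                raise NotRealizableError(
                    f"no realization on the requested support (column {q})"
                )
            vals = np.maximum(res.values, 0.0)
            for idx, p in enumerate(targets):
                if (q, p) in support:
                    A[p, q] = vals[idx]
        A -= np.diag(A.sum(axis=0))
        return ReactionNetwork(self.complexes, KirchhoffMatrix(A))

    def sparse(self, dense: DenseResult | None = None) -> SparseResult:
        """A realization with the globally minimal number of reactions.

        Every support returned by the MILP is re-verified with an exact LP
        feasibility check; a support the LP rejects (a numerically spurious
        MILP optimum) is removed with a no-good cut and the MILP re-solved.
        """
        dense = dense or self.dense()
        edges = sorted(dense.support.edges)
        idx = {e: i for i, e in enumerate(edges)}
        cuts: list[list[int]] = []
        for _ in range(len(edges) + 1):
            res = self._sparse_milp(dense, extra_cuts=cuts or None)
            if res.status == "infeasible":
                raise NotRealizableError("dynamics not realizable")
            if res.status != "optimal":
                raise RuntimeError(f"sparse MILP failed: {res.status} {res.message}")
            support = self._milp_support(res, dense)
            if self._verify_support(support):
                return SparseResult(
                    self._realize_on_support(support), support, len(support)
                )
            cuts.append([idx[e] for e in support])
        raise RuntimeError("sparse MILP did not converge to a verifiable support")

    def enumerate_sparse(
        self, max_count: int = 64, dense: DenseResult | None = None
    ) -> list[ReactionSupport]:
        """All distinct minimum-cardinality supports, via no-good cuts.

        After the first solve fixes the minimal cardinality, each found
        support ``S`` is cut off with ``sum_{e in S} delta_e <= |S| - 1``
        and the MILP re-solved until infeasibility (or ``max_count``).
        """
        if max_count < 1:
            raise CRNError("max_count must be at least 1")
        dense = dense or self.dense()
        first = self.sparse(dense)
        edges = sorted(dense.support.edges)
        idx = {e: i for i, e in enumerate(edges)}
        found = [first.support]
        cuts = [[idx[e] for e in first.support]]
        while len(found) < max_count:
            res = self._sparse_milp(
                dense, extra_cuts=cuts, total_cardinality=first.cardinality
            )
            if res.status == "infeasible":
                break
            if res.status != "optimal":
                raise RuntimeError(
                    f"enumeration MILP failed: {res.status} {res.message}"
                )
            sup = self._milp_support(res, dense)
            cuts.append([idx[e] for e in sup])
            if sup in found:  # defensive: the cut should have removed it
                break
            if self._verify_support(sup):
                found.append(sup)
        return sorted(found, key=lambda s: sorted(s.edges))

    def unique(self) -> tuple[bool, UniquenessWitness]:
        """Structural uniqueness test: dense and sparse supports coincide.

        Every realization's support lies between some sparse support and the
        dense one, so the structure is unique iff the dense support already
        has minimal cardinality.
        """
        dense = self.dense()
        sparse = self.sparse(dense)
        return (
            len(dense.support) == sparse.cardinality,
            UniquenessWitness(dense.support, sparse.support),
        )


# -- functional interface --------------------------------------------------


def edge_max_rate(Y, M, constraints, edge, **kwargs) -> float:
    return RealizationProblem(Y, M, constraints, **kwargs).edge_max(edge)


def dense_realization(Y, M, constraints=None, **kwargs) -> DenseResult:
    return RealizationProblem(Y, M, constraints, **kwargs).dense()


def sparse_realization(Y, M, constraints=None, **kwargs) -> SparseResult:
    return RealizationProblem(Y, M, constraints, **kwargs).sparse()


def enumerate_sparse_supports(
    Y, M, constraints=None, max_count: int = 64, **kwargs
) -> list[ReactionSupport]:
    return RealizationProblem(Y, M, constraints, **kwargs).enumerate_sparse(max_count)


def core_reactions(Y, M, constraints=None, **kwargs) -> CoreReport:
    return RealizationProblem(Y, M, constraints, **kwargs).core()


def is_structure_unique(
    Y, M, constraints=None, **kwargs
) -> tuple[bool, UniquenessWitness]:
    return RealizationProblem(Y, M, constraints, **kwargs).unique()
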