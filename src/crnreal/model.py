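"""Core data model for mass-action chemical reaction networks.

A chemical reaction network (CRN) over species ``X_1 .. X_n`` is described
by a set of *complexes* -- formal nonnegative-integer combinations of the
species, such as ``2 X1`` or ``X2 + X3`` -- and a set of directed reactions
between distinct complexes, each carrying a positive rate coefficient.

Two matrices capture the structure and kinetics:

* the composition matrix ``Y`` (``n x m``), whose column ``j`` holds the
  stoichiometric coefficients of complex ``C_j``;
* the Kirchhoff matrix ``A_k`` (``m x m``), whose off-diagonal entry
  ``A_k[i, j]`` is the rate coefficient of reaction ``C_j -> C_i`` and whose
  columns each sum to zero.

Under mass-action kinetics the species concentrations evolve as
``xdot = Y . A_k . psi(x)`` where ``psi_j(x) = prod_i x_i ** Y[i, j]`` is
the monomial map.  Two networks sharing a complex set are *dynamically
equivalent* -- they generate identical ODEs -- exactly when they share the
invariant matrix ``M = Y . A_k`` of monomial coefficients.  Everything in
this module reduces equivalence questions to linear algebra on ``M``; no
ODE is ever integrated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "CRNError",
    "ComplexMatrix",
    "KirchhoffMatrix",
    "ReactionNetwork",
    "ReactionSupport",
    "monomial_vector",
    "invariant_matrix",
    "evaluate_dynamics",
    "support",
    "check_dynamical_equivalence",
    "merge_complex_sets",
    "column_scales",
]

class CRNError(ValueError):
    """Invalid reaction-network data."""


def _as_int_matrix(Y) -> np.ndarray:
    arr = np.asarray(Y)
    if arr.ndim != 2:
        raise CRNError("composition matrix must be two-dimensional")
    if not np.issubdtype(arr.dtype, np.integer):
        rounded = np.rint(arr)
        if not np.allclose(arr, rounded, atol=1e-12):
            raise CRNError("stoichiometric coefficients must be integers")
        arr = rounded.astype(np.int64)
    else:
        arr = arr.astype(np.int64)
    if (arr < 0).any():
        raise CRNError("stoichiometric coefficients must be nonnegative")
    return arr


@dataclass(frozen=True)
class ComplexMatrix:
    """Species labels plus the ``n x m`` composition matrix ``Y``.

    Column ``j`` is the exponent vector of complex ``C_j``.  Columns must be
    pairwise distinct; a single all-zero column (the "zero complex", used for
    production and degradation reactions) is permitted.
    """

    species: tuple[str, ...]
    Y: np.ndarray

    def __init__(self, species: Iterable[str], Y) -> None:
        species = tuple(str(s) for s in species)
        arr = _as_int_matrix(Y)
        if len(set(species)) != len(species):
            raise CRNError("species labels must be distinct")
        if arr.shape[0] != len(species):
            raise CRNError(
                f"composition matrix has {arr.shape[0]} rows "
                f"for {len(species)} species"
            )
        cols = [tuple(c) for c in arr.T]
        if len(set(cols)) != len(cols):
            raise CRNError("complexes must be distinct")
        arr.setflags(write=False)
        object.__setattr__(self, "species", species)
        object.__setattr__(self, "Y", arr)

    @property
    def n_species(self) -> int:
        return self.Y.shape[0]

    @property
    def n_complexes(self) -> int:
        return self.Y.shape[1]

    def column(self, j: int) -> tuple[int, ...]:
        return tuple(self.Y[:, j])

    def label(self, j: int) -> str:
        """Human-readable formula of complex ``j`` (``"0"`` for the zero complex)."""
        terms = []
        for coeff, name in zip(self.Y[:, j], self.species):
            if coeff == 1:
                terms.append(name)
            elif coeff > 1:
                terms.append(f"{coeff} {name}")
        return " + ".join(terms) if terms else "0"

    def index_of(self, composition: Mapping[str, int] | tuple[int, ...]) -> int:
        """Index of the complex with the given composition.

        ``composition`` is either an exponent tuple in species order or a
        mapping from species label to coefficient (absent species are zero).
        """
        if isinstance(composition, Mapping):
            unknown = set(composition) - set(self.species)
            if unknown:
                raise CRNError(f"unknown species: {sorted(unknown)}")
            key = tuple(int(composition.get(s, 0)) for s in self.species)
        else:
            key = tuple(int(v) for v in composition)
        for j in range(self.n_complexes):
            if self.column(j) == key:
                return j
        raise CRNError(f"no such complex: {key}")

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, ComplexMatrix)
            and self.species == other.species
            and self.Y.shape == other.Y.shape
            and bool((self.Y == other.Y).all())
        )

    def __hash__(self) -> int:
        return hash((self.species, self.Y.tobytes()))


class KirchhoffMatrix:
    """Column-conservation matrix of rate coefficients.

    Off-diagonal entry ``A[i, j]`` is the rate coefficient of the reaction
    from complex ``j`` to complex ``i``; the diagonal makes every column sum
    to zero.  Small solver noise (relative to the matrix scale) is tolerated
    on the sign constraints but the column sums must vanish.
    """

    __slots__ = ("A",)

    def __init__(self, A) -> None:
        arr = np.array(A, dtype=float)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise CRNError("Kirchhoff matrix must be square")
        scale = max(1.0, float(np.abs(arr).max(initial=0.0)))
        off = arr[~np.eye(arr.shape[0], dtype=bool)]
        if off.size and off.min(initial=0.0) < -1e-8 * scale:
            raise CRNError("off-diagonal Kirchhoff entries must be nonnegative")
        if np.diag(arr).max(initial=0.0) > 1e-8 * scale:
            raise CRNError("diagonal Kirchhoff entries must be nonpositive")
        colsums = arr.sum(axis=0)
        if np.abs(colsums).max(initial=0.0) > 1e-8 * scale:
            raise CRNError("Kirchhoff columns must sum to zero")
        arr.setflags(write=False)
        self.A = arr

    @classmethod
    def from_reactions(
        cls, m: int, rates: Mapping[tuple[int, int], float]
    ) -> "KirchhoffMatrix":
        """Build from ``{(source, target): rate}`` with 0-based complex indices."""
        A = np.zeros((m, m))
        for (src, tgt), k in rates.items():
            if src == tgt:
                raise CRNError(f"self-loop reaction on complex {src}")
            if not (0 <= src < m and 0 <= tgt < m):
                raise CRNError(f"reaction ({src}, {tgt}) out of range")
            if k <= 0:
                raise CRNError(f"rate for reaction ({src}, {tgt}) must be positive")
            A[tgt, src] += k
        np.fill_diagonal(A, 0.0)
        A -= np.diag(A.sum(axis=0))
        return cls(A)

    @property
    def m(self) -> int:
        return self.A.shape[0]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, KirchhoffMatrix)
            and self.A.shape == other.A.shape
            and bool((self.A == other.A).all())
        )

    def __repr__(self) -> str:
        return f"KirchhoffMatrix(m={self.m})"


class ReactionSupport:
    """An unweighted reaction graph: a set of ordered complex-index pairs.

    Edges are ``(source, target)`` pairs with 0-based indices and
    ``source != target``.  Supports behave like immutable sets and support
    the usual set algebra, which is how super-structure and core-containment
    statements are phrased.
    """

    __slots__ = ("edges",)

    def __init__(self, edges: Iterable[tuple[int, int]], m: int | None = None):
        es = frozenset((int(a), int(b)) for a, b in edges)
        for a, b in es:
            if a == b:
                raise CRNError(f"self-loop edge ({a}, {b}) not allowed")
            if a < 0 or b < 0 or (m is not None and (a >= m or b >= m)):
                raise CRNError(f"edge ({a}, {b}) out of range")
        self.edges = es

    def __len__(self) -> int:
        return len(self.edges)

    def __iter__(self) -> Iterator[tuple[int, int]]:
        return iter(sorted(self.edges))

    def __contains__(self, edge) -> bool:
        return tuple(edge) in self.edges

    def __eq__(self, other) -> bool:
        if isinstance(other, ReactionSupport):
            return self.edges == other.edges
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self.edges)

    def __le__(self, other: "ReactionSupport") -> bool:
        return self.edges <= other.edges

    def issubset(self, other: "ReactionSupport") -> bool:
        return self.edges <= other.edges

    def union(self, other: "ReactionSupport") -> "ReactionSupport":
        return ReactionSupport(self.edges | other.edges)

    def intersection(self, other: "ReactionSupport") -> "ReactionSupport":
        return ReactionSupport(self.edges & other.edges)

    def difference(self, other: "ReactionSupport") -> "ReactionSupport":
        return ReactionSupport(self.edges - other.edges)

    def __repr__(self) -> str:
        return f"ReactionSupport({sorted(self.edges)})"


class ReactionNetwork:
    """A mass-action CRN: a complex set plus a Kirchhoff matrix."""

    __slots__ = ("complexes", "kinetics")

    def __init__(self, complexes: ComplexMatrix, kinetics: KirchhoffMatrix):
        if complexes.n_complexes != kinetics.m:
            raise CRNError(
                f"{complexes.n_complexes} complexes but Kirchhoff matrix "
                f"of size {kinetics.m}"
            )
        self.complexes = complexes
        self.kinetics = kinetics

    @classmethod
    def from_reactions(
        cls,
        species: Iterable[str],
        compositions: Iterable[Mapping[str, int]],
        reactions: Mapping[tuple[int, int], float],
    ) -> "ReactionNetwork":
        """Build a network from complex compositions and indexed reactions."""
        species = tuple(species)
        comps = list(compositions)
        Y = np.zeros((len(species), len(comps)), dtype=np.int64)
        for j, comp in enumerate(comps):
            for name, coeff in comp.items():
                Y[species.index(name), j] = coeff
        cm = ComplexMatrix(species, Y)
        return cls(cm, KirchhoffMatrix.from_reactions(cm.n_complexes, reactions))

    @property
    def n_species(self) -> int:
        return self.complexes.n_species

    @property
    def n_complexes(self) -> int:
        return self.complexes.n_complexes

    def invariant_matrix(self) -> np.ndarray:
        return invariant_matrix(self)

    def support(self, tol: float = 0.0) -> ReactionSupport:
        return support(self.kinetics, tol)

    def __call__(self, x) -> np.ndarray:
        return evaluate_dynamics(self, x)


def monomial_vector(Y: ComplexMatrix | np.ndarray, x) -> np.ndarray:
    """Evaluate the monomial map ``psi_j(x) = prod_i x_i ** Y[i, j]``.

    The zero complex (all-zero column) evaluates to 1, the empty product.
    """
    arr = Y.Y if isinstance(Y, ComplexMatrix) else _as_int_matrix(Y)
    x = np.asarray(x, dtype=float)
    if x.shape != (arr.shape[0],):
        raise CRNError(f"state of length {x.size} for {arr.shape[0]} species")
    if (x < 0).any():
        raise CRNError("species concentrations must be nonnegative")
    # 0.0 ** 0 == 1.0, so the empty-product convention holds entrywise.
    return np.prod(x[:, None] ** arr, axis=0)


def invariant_matrix(net: ReactionNetwork) -> np.ndarray:
    """The monomial-coefficient matrix ``M = Y . A_k``.

    Row ``i``, column ``j`` is the coefficient of monomial ``psi_j`` in the
    ODE for species ``i``.  ``M`` is the complete fingerprint of the
    dynamics: every dynamically equivalent realization on the same complex
    set shares it.
    """
    return net.complexes.Y @ net.kinetics.A


def evaluate_dynamics(net: ReactionNetwork, x) -> np.ndarray:
    """Right-hand side ``Y . A_k . psi(x)`` of the mass-action ODE."""
    return invariant_matrix(net) @ monomial_vector(net.complexes, x)


def support(A: KirchhoffMatrix | np.ndarray, tol: float = 0.0) -> ReactionSupport:
    """Edges ``(j, i)`` whose rate coefficient ``A[i, j]`` strictly exceeds ``tol``.

    Entries exactly equal to ``tol`` are excluded (strict inequality), so a
    tolerance of 0 keeps exactly the nonzero rates.
    """
    if tol < 0:
        raise CRNError("tolerance must be nonnegative")
    arr = A.A if isinstance(A, KirchhoffMatrix) else np.asarray(A, dtype=float)
    m = arr.shape[0]
    edges = [
        (j, i) for i in range(m) for j in range(m) if i != j and arr[i, j] > tol
    ]
    return ReactionSupport(edges, m)


def column_scales(M: np.ndarray) -> np.ndarray:
    """Per-column natural scale ``max(1, ||M[:, j]||_inf)`` of an invariant matrix."""
    M = np.atleast_2d(np.asarray(M, dtype=float))
    return np.maximum(1.0, np.abs(M).max(axis=0, initial=0.0))


def merge_complex_sets(
    Y1: ComplexMatrix, Y2: ComplexMatrix
) -> tuple[ComplexMatrix, list[int], list[int]]:
    """Union of two complex sets over the same species universe.

    Returns the deduplicated union in canonical order (columns sorted
    lexicographically by exponent vector) together with the column maps of
    each input into the union.  The operation is idempotent and insensitive
    to argument order.
    """
    if set(Y1.species) != set(Y2.species):
        raise CRNError("complex sets are over different species universes")
    # express Y2 in Y1's species order
    perm = [Y2.species.index(s) for s in Y1.species]
    cols1 = [Y1.column(j) for j in range(Y1.n_complexes)]
    cols2 = [tuple(Y2.Y[perm, j]) for j in range(Y2.n_complexes)]
    union = sorted(set(cols1) | set(cols2))
    lookup = {c: j for j, c in enumerate(union)}
    merged = ComplexMatrix(Y1.species, np.array(union, dtype=np.int64).T)
    return merged, [lookup[c] for c in cols1], [lookup[c] for c in cols2]


def check_dynamical_equivalence(
    net1: ReactionNetwork, net2: ReactionNetwork, tol: float = 1e-9
) -> bool:
    """Decide whether two networks generate identical mass-action ODEs.

    The comparison is purely algebraic: both invariant matrices are embedded
    into the union of the two complex sets (zero columns for complexes a
    network lacks) and compared in the max norm, relative to the scale of the
    first network's invariant matrix.  Species sets must agree; their order
    may differ.
    """
    if set(net1.complexes.species) != set(net2.complexes.species):
        raise CRNError("networks are over different species sets")
    merged, map1, map2 = merge_complex_sets(net1.complexes, net2.complexes)
    n = net1.n_species
    M1 = np.zeros((n, merged.n_complexes))
    M2 = np.zeros((n, merged.n_complexes))
    M1[:, map1] = invariant_matrix(net1)
    perm = [net2.complexes.species.index(s) for s in net1.complexes.species]
    M2[:, map2] = invariant_matrix(net2)[perm]
    scale = max(1.0, float(np.abs(M1).max(initial=0.0)))
    return bool(np.abs(M1 - M2).max(initial=0.0) <= tol * scale)
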