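"""Structural identifiability of sparse linear gene-network models.

Gene regulatory networks are often modelled as linear time-invariant systems
``xdot = A x + B u`` where ``A[i, j] != 0`` means gene ``j`` regulates gene
``i`` (positive: activation, negative: repression; diagonal entries are
autoregulation) and the input ``B u`` is an experimental perturbation of one
gene.  With zero initial conditions, only genes reachable from the perturbed
gene along directed influence edges ``j -> i`` ever move, so full
reachability of the influence graph from the perturbed node is a necessary
condition for structural identifiability of ``A``.  This module generates
random sparse sign patterns (a fixed number of regulators per gene) and
measures by Monte Carlo how often that necessary condition fails.

Only the reachability condition is tested; rank/observability conditions
and practical identifiability are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt
from types import MappingProxyType
from typing import Mapping

import numpy as np

__all__ = [
    "SignPattern",
    "MCResult",
    "reachable_nodes",
    "generate_sparse_linear_model",
    "nonidentifiable_fraction",
    "reachable_size_histogram",
    "ten_gene_example_pattern",
]

_SIGNS = ("+", "-", "*")  # activation, repression, nonzero of undetermined sign


@dataclass(frozen=True)
class SignPattern:
    """Sign pattern of an ``n x n`` connectivity matrix.

    ``entries[(i, j)]`` is the sign of ``A[i, j]``; a present key means the
    influence ``j -> i`` exists.  Signs are irrelevant to reachability but
    are kept so patterns can be rendered and checked.
    """

    n: int
    entries: Mapping[tuple[int, int], str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", MappingProxyType(dict(self.entries)))
        for (i, j), sign in self.entries.items():
            if not (0 <= i < self.n and 0 <= j < self.n):
                raise ValueError(f"entry ({i}, {j}) out of range for n={self.n}")
            if sign not in _SIGNS:
                raise ValueError(f"invalid sign {sign!r}")

    def adjacency(self) -> np.ndarray:
        """Boolean matrix with ``adj[i, j]`` true iff ``j`` influences ``i``."""
        adj = np.zeros((self.n, self.n), dtype=bool)
        for i, j in self.entries:
            adj[i, j] = True
        return adj


@dataclass(frozen=True)
class MCResult:
    """Monte Carlo estimate of the structurally non-identifiable fraction."""

    n: int
    k: int
    trials: int
    non_identifiable: int
    seed: int
    include_diagonal: bool

    @property
    def fraction(self) -> float:
        return self.non_identifiable / self.trials

    @property
    def std_error(self) -> float:
        f = self.fraction
        return sqrt(f * (1.0 - f) / self.trials)


def _reach(adj: np.ndarray, source: int) -> frozenset[int]:
    n = adj.shape[0]
    seen = np.zeros(n, dtype=bool)
    seen[source] = True
    stack = [source]
    while stack:
        j = stack.pop()
        for i in np.nonzero(adj[:, j] & ~seen)[0]:
            seen[i] = True
            stack.append(int(i))
    return frozenset(np.nonzero(seen)[0].tolist())


def reachable_nodes(pattern: SignPattern, source: int) -> frozenset[int]:
    """Nodes reachable from ``source`` by depth-first search along ``j -> i`` edges."""
    if not 0 <= source < pattern.n:
        raise ValueError(f"node {source} out of range for n={pattern.n}")
    return _reach(pattern.adjacency(), source)


def generate_sparse_linear_model(
    n: int, k: int, rng: np.random.Generator, include_diagonal: bool = True
) -> SignPattern:
    """Random sign pattern with exactly ``k`` regulators (nonzeros) per row.

    Column positions are drawn uniformly without replacement; with
    ``include_diagonal`` (the default) the diagonal — autoregulation — may be
    among them.  Signs are drawn uniformly from ``{+, -}``.
    """
    if not 1 <= k <= (n if include_diagonal else n - 1):
        raise ValueError(f"need 1 <= k <= {'n' if include_diagonal else 'n-1'}")
    entries: dict[tuple[int, int], str] = {}
    for i in range(n):
        pool = np.arange(n) if include_diagonal else np.delete(np.arange(n), i)
        cols = rng.choice(pool, size=k, replace=False)
        signs = rng.choice(("+", "-"), size=k)
        for j, s in zip(cols, signs):
            entries[(i, int(j))] = str(s)
    return SignPattern(n, entries)


def _mc_reach_sizes(
    n: int,
    k: int,
    trials: int,
    seed: int,
    include_diagonal: bool,
    perturbed: int,
) -> np.ndarray:
    rng = np.random.default_rng(seed)
    sizes = np.empty(trials, dtype=np.int64)
    for t in range(trials):
        pattern = generate_sparse_linear_model(n, k, rng, include_diagonal)
        sizes[t] = len(_reach(pattern.adjacency(), perturbed))
    return sizes


def nonidentifiable_fraction(
    n: int,
    k: int,
    trials: int,
    seed: int,
    include_diagonal: bool = True,
    perturbed: int = 0,
) -> MCResult:
    """Monte Carlo fraction of models failing the reachability condition.

    A model counts as structurally non-identifiable when not every node is
    reachable from the perturbed node (node 1 by default; the generator is
    exchangeable over node labels so the choice does not matter).
    Deterministic for a given seed.
    """
    if trials < 1:
        raise ValueError("trials must be at least 1")
    sizes = _mc_reach_sizes(n, k, trials, seed, include_diagonal, perturbed)
    return MCResult(
        n=n,
        k=k,
        trials=trials,
        non_identifiable=int((sizes < n).sum()),
        seed=seed,
        include_diagonal=include_diagonal,
    )


def reachable_size_histogram(
    n: int,
    k: int,
    trials: int,
    seed: int,
    include_diagonal: bool = True,
    perturbed: int = 0,
) -> np.ndarray:
    """Counts of reachable-set sizes 1..n over the Monte Carlo draws."""
    sizes = _mc_reach_sizes(n, k, trials, seed, include_diagonal, perturbed)
    return np.bincount(sizes, minlength=n + 1)[1:]


# 10-gene benchmark pattern (11 activations, 6 repressions, 3 autoregulation
# links of undetermined sign at genes 1, 3 and 6; exactly 2 regulators per
# gene).  Exciting gene 1 or 2 reaches nothing else, so the remaining
# connections are undetectable from such an experiment.
_TEN_GENE_ROWS = (
    "*0000000+0",
    "0000000++0",
    "00*00-0000",
    "000000+00+",
    "000+000-00",
    "00000*00+0",
    "00++000000",
    "0000-0-000",
    "00000-+000",
    "000000+-00",
)


def ten_gene_example_pattern() -> SignPattern:
    """The worked 10-gene sparse network used in the identifiability example."""
    entries = {
        (i, j): ch
        for i, row in enumerate(_TEN_GENE_ROWS)
        for j, ch in enumerate(row)
        if ch != "0"
    }
    return SignPattern(10, entries)
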