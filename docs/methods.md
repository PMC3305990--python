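# Methods

## Model

A mass-action CRN is `(Y, A_k)`: `Y ∈ Z_{≥0}^{n×m}` holds the complex
compositions (distinct columns; at most one all-zero column, the zero complex
used by production/degradation reactions), and `A_k ∈ R^{m×m}` is Kirchhoff:
off-diagonal entries are nonnegative rate coefficients, every column sums to
zero, self-loops do not exist. The species ODE is `ẋ = Y·A_k·ψ(x)` with the
monomial map `ψ_j(x) = ∏_i x_i^{Y[i,j]}` (empty product = 1 for the zero
complex). Everything this package computes rests on one reduction: with the
complex set fixed, dynamical equivalence of `(Y, A_k)` and `(Y, A_k')` is the
linear condition `Y·A_k = Y·A_k' = M`. Equivalence testing is therefore purely
algebraic — networks with different complex sets are compared by embedding
both invariant matrices into the ordered union of the complex sets and
comparing in the max norm (relative tolerance `1e-9` by default) — and no ODE
is ever integrated.

## Realization algorithms

Let `M` be the invariant matrix and `K` an optional set of excluded reactions
(entries of `A_k` forced to zero). All computations run over the polyhedron

```
P(K) = { A_k Kirchhoff : Y·A_k = M, A_k[p,q] = 0 for (q,p) ∈ K }
```

**Column decomposition.** No constraint of `P(K)` couples two columns of
`A_k`, and within column `q` the diagonal entry is determined by the column
sum, so substituting `A[q,q] = −Σ_p A[p,q]` turns the column into the system
`Σ_{p≠q} (Y[:,p] − Y[:,q])·a_p = M[:,q]`, `a_p ∈ [0, U_q]`. Every LP and MILP
below is posed on these per-column programs (m−1 variables, n equality rows)
instead of one `m(m−1)`-variable program. This is an exact reformulation, not
an approximation; the test suite cross-checks it against an independent
full-matrix LP oracle on small networks.

**Dense realization.** For every admissible ordered pair `(q,p)` an LP
maximises `A[p,q]` over `P(K)`; the edge `C_q → C_p` is in the dense support
iff the maximum is positive. The returned dense *realization* is assembled per
column by a feasibility LP whose lower bounds come from the average of that
column's edge-maximising optimizers — a convex combination of feasible
columns, hence itself feasible, and positive exactly on the dense support
(lower bounds are capped at `10·zero_tol` so they can never collide with
solver feasibility tolerances). The dense support is a super-structure: the
graph of every realization in `P(K)` is a subgraph of it, and it is unique,
which the suite asserts by recomputing it under complex permutations and
different upper bounds.

**Core reactions.** For each dense edge, one LP feasibility check on `P(K)`
with that single edge additionally forced to zero; the edge is core iff the
program is infeasible. Core reactions are present in every equivalent
realization; non-core reactions can each be dropped individually (though not
necessarily jointly).

**Sparse realizations.** A MILP over the dense support (justified by the
super-structure property): binary indicators `δ_e`, linking rows
`a_e ≤ U_e·δ_e`, objective `min Σ δ_e`. `U_e` is the edge's maximal rate from
the dense sweep — the tightest valid big-M. Because MILP integrality/
feasibility tolerances could still fake a support, every claimed support is
re-verified by an exact LP feasibility check restricted to it; a support the
LP rejects is removed with a no-good cut and the MILP re-solved. All distinct
minimum-cardinality supports are enumerated by fixing `Σ δ_e` to the minimum
and iterating cuts `Σ_{e∈S} δ_e ≤ |S|−1` until infeasibility; supports are
canonicalised as sorted edge lists.

**Uniqueness.** The structure of `P(K)` is unique iff the dense and sparse
supports coincide, i.e. iff `|dense|` equals the minimal cardinality; the
test returns that verdict plus both supports as a witness.

## Numerical choices

- **Raw units, absolute zero threshold.** Programs are given to HiGHS
  unscaled. Realistic rate sets span many decades *within one column* (the
  feedback motif mixes `1e7` and `2.5e-2`), so any tolerance proportional to
  `‖M‖` misclassifies small rates, and normalising a column squashes its small
  entries below the solver's feasibility tolerance. HiGHS's internal
  equilibration handles the spread; on all built-in systems the maxima of
  absent edges come back exactly zero. An edge counts as present iff its
  maximal rate exceeds `zero_tol` (default `1e-7`, configurable) — far above
  solver noise, far below meaningful rate coefficients. Models whose real
  rates approach `1e-7` need a smaller `zero_tol`.
- **Upper bounds.** `U_q = u_scale · max(1, ‖M[:,q]‖_∞)` with
  `u_scale = 1000`. Dense membership is U-independent (asserted in tests);
  returned rate values are not, which is why the CLI logs the configuration.
- **Determinism.** One solver (HiGHS via SciPy), fixed configuration,
  sequential deterministic sweep order; identical inputs give identical
  supports, maxima and MILP outcomes. Tie-breaking among multiple MILP optima
  is solver-dependent, so enumeration — not the order of a single solve — is
  the supported way to obtain all minimal structures.
- **Degenerate inputs.** A column whose reactions are all excluded is
  realizable only if its dynamics vanish; infeasibility anywhere raises a
  dedicated "not realizable" error (CLI exit code 3), distinct from an edge
  merely being absent.

## Example systems and rate sampling

The three built-in CRNs are constructed programmatically from their reaction
lists: the positive feedback motif (5 species, 11 complexes, 9 reactions, with
a standard rate set spanning `1e7`–`2.5e-2` and an optional 12th complex
`X2+X4`), the yeast Sic1/Clb/Cdc14 switch (9 species, 17 complexes, 18
reactions) and a 5-gene auto-activating repressilator ring (25 species, 51
complexes, 55 reactions, zero complex shared by the protein degradations).

The switch and repressilator have no published rate values; their analysed
properties (dense/core/sparse supports) are *structural* — piecewise-constant
in the rates and constant on a full-measure set — so the constructors take a
seeded uniform sampler on `[0.5, 20.5)` (a generic, dimensionless "order 1–20"
range) and every claim is confirmed at two seeds. Passing tests therefore
certify the generic-parameter structure, not any particular biological
parametrisation; a fine-tuned (measure-zero) rate set could in principle admit
extra realizations.

## Linear-GRN identifiability Monte Carlo

Sparse linear gene-network models `ẋ = Ax + Bu` are sampled as sign patterns
with exactly `k` nonzeros per row (row `i` lists the regulators of gene `i`,
i.e. `A[i,j] ≠ 0` is an influence `j → i`). Positions are uniform without
replacement; `include_diagonal=True` (default) lets autoregulation occupy one
of the `k` slots. Signs are drawn uniformly and recorded but play no role in
reachability. With a single perturbed gene and zero initial state, only genes
reachable from the perturbed one along influence edges ever move, so full
reachability (depth-first search from node 1; the generator is exchangeable
over labels) is a *necessary* condition for structural identifiability — no
rank/observability condition is checked, so the reported fraction is a lower
bound on the truly non-identifiable fraction. Results are deterministic given
`(n, k, trials, seed)`; a histogram of reachable-set sizes is available.

Caveat: this criterion is sensitive to the orientation convention of the
connectivity matrix. With the convention above and default settings
(`n=10, k=2`, 10000 trials) about 23–24% of models fail the condition;
transposing the adjacency (equivalently, fixing the number of *targets* per
gene instead of regulators) yields ~70–80%. Published figures for comparable
experiments vary accordingly; both the generator flag and the perturbed node
are explicit parameters so either convention can be examined.

## Problem sizes and runtime

The dense sweep of the repressilator — 2550 LPs of 50 variables — takes a few
seconds on one CPU thanks to the column decomposition; its sparse MILP has 70
binaries and solves in well under a second. The acceptance script (all three
CRNs at two seeds each, plus a 10000-trial Monte Carlo) completes in roughly
15 seconds; the full test suite, including exhaustive subset oracles on small
networks, in well under a minute.

## Known limitations

- Mass-action kinetics only; no rational/Hill kinetics, no stochastic
  semantics, no time-domain simulation.
- The complex set must be fixed a priori; realizations with more/fewer
  complexes, reversibility- or balance-constrained realizations, and linear
  conjugacy transformations are out of scope.
- Structural uniqueness reduces, but does not imply, parameter
  identifiability; the GRN module tests only the necessary reachability
  condition.
- Exchange format is the package's own plain-text reaction syntax; SBML is
  not parsed.
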