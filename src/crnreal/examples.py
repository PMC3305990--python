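"""Built-in example systems: programmatic constructors, no external data.

Three mass-action CRNs from the gene-regulation / cell-cycle literature:

* a positive feedback motif (a gene promoting its own transcription after
  dimerization; 5 species, 11 complexes, 9 reactions), optionally extended
  with one extra complex;
* a biochemical switch from yeast cell-cycle regulation (Sic1/Clb/Cdc14;
  9 species, 17 complexes, 18 reactions);
* a 5-gene repressilator with auto-activation (25 species, 51 complexes,
  55 reactions).

The switch and repressilator carry no published rate values; their
structural properties are rate-independent, so their constructors take a
seeded uniform sampler and tests exercise them at two seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import ComplexMatrix, CRNError, KirchhoffMatrix, ReactionNetwork
from .realize import ConstraintSet

__all__ = [
    "RateSampler",
    "random_rates",
    "positive_feedback_network",
    "yeast_switch_network",
    "repressilator_network",
    "POSITIVE_FEEDBACK_RATES",
    "POSITIVE_FEEDBACK_ALT_RATES",
    "YEAST_SWITCH_UNIQUENESS_EXCLUSIONS",
]


@dataclass
class RateSampler:
    """Seeded uniform sampler of positive rate coefficients on ``[low, high)``."""

    seed: int
    low: float = 0.5
    high: float = 20.5

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise CRNError("need 0 < low < high")
        self._rng = np.random.default_rng(self.seed)

    def draw(self, count: int) -> np.ndarray:
        return self._rng.uniform(self.low, self.high, size=count)


def random_rates(seed: int, low: float = 0.5, high: float = 20.5) -> RateSampler:
    return RateSampler(seed, low, high)


# -- positive feedback motif ------------------------------------------------

#: standard parametrization: dimerization/promoter (de)binding at 1e7 M^-1,
#: activated transcription 1.7, basal transcription 0.025, mRNA degradation
#: 0.1, monomer degradation 0.05, translation 0.5 (min^-1)
POSITIVE_FEEDBACK_RATES = (1e7, 1e7, 1e7, 1e7, 1.7, 0.025, 0.1, 0.05, 0.5)

#: an alternative (arbitrary) parametrization with the same structure but a
#: different core-reaction set
POSITIVE_FEEDBACK_ALT_RATES = (18.9, 7.1, 15.4, 12.7, 10.6, 3.5, 11.3, 9.1, 4.0)

# complexes in declared order; X1/X2 protein monomer/dimer, X3/X4 free and
# occupied promoter, X5 mRNA
_PF_COMPLEXES = (
    {"X1": 2},            # C1  2 X1
    {"X2": 1},            # C2  X2
    {"X2": 1, "X3": 1},   # C3  X2 + X3
    {"X4": 1},            # C4  X4
    {"X4": 1, "X5": 1},   # C5  X4 + X5
    {"X3": 1},            # C6  X3
    {"X3": 1, "X5": 1},   # C7  X3 + X5
    {"X5": 1},            # C8  X5
    {},                   # C9  0   (degradation products)
    {"X1": 1},            # C10 X1
    {"X1": 1, "X5": 1},   # C11 X1 + X5
)

# reaction list as 1-based (source, target) pairs for rates k1..k9:
# dimerization/dissociation, promoter binding/unbinding, activated and basal
# transcription, mRNA and monomer degradation, translation
_PF_REACTIONS = ((1, 2), (2, 1), (3, 4), (4, 3), (4, 5), (6, 7), (8, 9), (10, 9), (8, 11))


def positive_feedback_network(rates=None, extended: bool = False) -> ReactionNetwork:
    """The positive feedback motif; ``extended`` adds the complex X2 + X4.

    The extra complex changes no reaction but enlarges the space of
    dynamically equivalent realizations.
    """
    rates = POSITIVE_FEEDBACK_RATES if rates is None else tuple(rates)
    if len(rates) != 9:
        raise CRNError("the motif takes 9 rate coefficients")
    if any(k <= 0 for k in rates):
        raise CRNError("rate coefficients must be positive")
    complexes = _PF_COMPLEXES + ({"X2": 1, "X4": 1},) if extended else _PF_COMPLEXES
    reactions = {
        (src - 1, tgt - 1): k for (src, tgt), k in zip(_PF_REACTIONS, rates)
    }
    return ReactionNetwork.from_reactions(
        ("X1", "X2", "X3", "X4", "X5"), complexes, reactions
    )


# -- yeast biochemical switch ----------------------------------------------

_YEAST_SPECIES = (
    "Sic1", "Sic1P", "Clb", "Clb.Sic1", "Clb.Sic1P",
    "Cdc14", "Sic1P.Cdc14", "Clb.Sic1P.Cdc14", "Clb.Sic1.Clb",
)

# composition matrix, one row (9 digits, species order above) per complex
_YEAST_COMPLEX_ROWS = (
    "010000000",  # C1  Sic1P
    "000000000",  # C2  0
    "100000000",  # C3  Sic1
    "101000000",  # C4  Sic1 + Clb
    "000100000",  # C5  Clb.Sic1
    "001000000",  # C6  Clb
    "011000000",  # C7  Sic1P + Clb
    "000010000",  # C8  Clb.Sic1P
    "001100000",  # C9  Clb + Clb.Sic1
    "000000001",  # C10 Clb.Sic1.Clb
    "001010000",  # C11 Clb + Clb.Sic1P
    "010001000",  # C12 Sic1P + Cdc14
    "000000100",  # C13 Sic1P.Cdc14
    "100001000",  # C14 Sic1 + Cdc14
    "000011000",  # C15 Clb.Sic1P + Cdc14
    "000000010",  # C16 Clb.Sic1P.Cdc14
    "000101000",  # C17 Clb.Sic1 + Cdc14
)

# 18 reactions as 1-based (source, target) pairs, in rate-index order k1..k18
_YEAST_REACTIONS = (
    (2, 3), (3, 2), (1, 2),            # Sic1 production/degradation, Sic1P degradation
    (4, 5), (5, 4), (5, 6),            # Clb+Sic1 <-> Clb.Sic1 -> Clb
    (7, 8), (8, 7), (8, 6),            # Sic1P+Clb <-> Clb.Sic1P -> Clb
    (9, 10), (10, 9), (10, 11),        # Clb+Clb.Sic1 <-> trimer -> Clb+Clb.Sic1P
    (12, 13), (13, 12), (13, 14),      # Sic1P+Cdc14 <-> complex -> Sic1+Cdc14
    (15, 16), (16, 15), (16, 17),      # Clb.Sic1P+Cdc14 <-> complex -> Clb.Sic1+Cdc14
)


def yeast_switch_network(sampler: RateSampler) -> ReactionNetwork:
    """The Sic1/Clb/Cdc14 switch with sampled positive rate coefficients."""
    Y = np.array([[int(c) for c in row] for row in _YEAST_COMPLEX_ROWS]).T
    cm = ComplexMatrix(_YEAST_SPECIES, Y)
    rates = sampler.draw(len(_YEAST_REACTIONS))
    reactions = {
        (src - 1, tgt - 1): float(k) for (src, tgt), k in zip(_YEAST_REACTIONS, rates)
    }
    return ReactionNetwork(cm, KirchhoffMatrix.from_reactions(cm.n_complexes, reactions))


def _yeast_exclusions() -> ConstraintSet:
    # the four exclusions that make the switch structure unique:
    # Clb.Sic1P -> Clb + Clb.Sic1P, Clb.Sic1 -> Clb + Clb.Sic1,
    # Sic1P + Clb -> Clb + Clb.Sic1P, Clb + Sic1 -> Clb + Clb.Sic1
    pairs_1based = ((8, 11), (5, 9), (7, 11), (4, 9))
    return ConstraintSet(((a - 1, b - 1) for a, b in pairs_1based), m=17)


YEAST_SWITCH_UNIQUENESS_EXCLUSIONS = _yeast_exclusions()


# -- repressilator ----------------------------------------------------------


def repressilator_network(sampler: RateSampler, n_genes: int = 5) -> ReactionNetwork:
    """Ring of ``n_genes`` genes, each repressed by its predecessor and
    auto-activated by its own protein.

    Per gene: cooperative binding of its own protein (activation) and of the
    repressor protein to the free and activated gene, single-step protein
    production from the activated and doubly-bound states (leaky), and
    first-order protein degradation -- 11 reactions, with genes conserved
    within each linkage class.  For 5 genes: 25 species, 51 distinct
    complexes (the degradation product is the shared zero complex) and 55
    reactions.
    """
    if n_genes < 2:
        raise CRNError("the ring needs at least 2 genes")
    species: list[str] = []
    for i in range(1, n_genes + 1):
        species += [f"G{i}", f"G{i}A", f"G{i}R", f"G{i}AR", f"P{i}"]

    compositions: list[dict[str, int]] = []
    index: dict[tuple, int] = {}

    def cx(comp: dict[str, int]) -> int:
        key = tuple(sorted(comp.items()))
        if key not in index:
            index[key] = len(compositions)
            compositions.append(comp)
        return index[key]

    reactions: dict[tuple[int, int], float] = {}

    def add(src: dict[str, int], tgt: dict[str, int], k: float) -> None:
        reactions[(cx(src), cx(tgt))] = float(k)

    for i in range(1, n_genes + 1):
        j = n_genes if i == 1 else i - 1  # repressor: previous gene in the ring
        g, ga, gr, gar = f"G{i}", f"G{i}A", f"G{i}R", f"G{i}AR"
        pi, pj = f"P{i}", f"P{j}"
        k = sampler.draw(11)
        add({g: 1, pi: 1}, {ga: 1}, k[0])          # auto-activation (binding)
        add({ga: 1}, {g: 1, pi: 1}, k[1])
        add({ga: 1}, {ga: 1, pi: 1}, k[2])         # protein production
        add({g: 1, pj: 1}, {gr: 1}, k[3])          # repression (binding)
        add({gr: 1}, {g: 1, pj: 1}, k[4])
        add({gr: 1, pi: 1}, {gar: 1}, k[5])        # activation of repressed gene
        add({gar: 1}, {gr: 1, pi: 1}, k[6])
        add({ga: 1, pj: 1}, {gar: 1}, k[7])        # repression of activated gene
        add({gar: 1}, {ga: 1, pj: 1}, k[8])
        add({gar: 1}, {gar: 1, pi: 1}, k[9])       # leaky production
        add({pi: 1}, {}, k[10])                    # protein degradation
    return ReactionNetwork.from_reactions(species, compositions, reactions)
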