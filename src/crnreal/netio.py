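"""Plain-text reaction-network exchange format and constraint files.

A network document is a species declaration followed by one reaction per
line::

    species X1 X2 X3 X4 X5
    2 X1 -> X2 ; k=1e7
    X5 -> 0 ; k=0.1

Complexes are ``+``-separated terms ``[<int>] <species>``; ``0`` denotes the
zero complex.  Lines starting with ``#`` and blank lines are ignored.
Parsing deduplicates complexes and orders them canonically; writing is
deterministic, and rates survive a round trip to 12 significant digits.

Constraint documents list excluded reactions with the same complex syntax,
one ``complex -> complex`` pair per line, no rate.
"""

from __future__ import annotations

import re

import numpy as np

from .model import ComplexMatrix, KirchhoffMatrix, ReactionNetwork
from .realize import ConstraintSet

__all__ = ["NetworkFormatError", "read_network", "write_network", "read_constraints"]


class NetworkFormatError(ValueError):
    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line else message)


_TERM = re.compile(r"^(?:(\d+)\s+)?([A-Za-z_][\w.]*)$")


def _parse_complex(text: str, species: tuple[str, ...], lineno: int) -> tuple[int, ...]:
    text = text.strip()
    if text == "0":
        return (0,) * len(species)
    comp = [0] * len(species)
    for term in text.split("+"):
        mt = _TERM.match(term.strip())
        if not mt:
            raise NetworkFormatError(f"malformed stoichiometry {term.strip()!r}", lineno)
        coeff = int(mt.group(1) or 1)
        name = mt.group(2)
        if coeff < 1:
            raise NetworkFormatError(f"zero coefficient in {term.strip()!r}", lineno)
        if name not in species:
            raise NetworkFormatError(f"unknown species {name!r}", lineno)
        comp[species.index(name)] += coeff
    return tuple(comp)


def _format_complex(column: tuple[int, ...], species: tuple[str, ...]) -> str:
    terms = []
    for coeff, name in zip(column, species):
        if coeff == 1:
            terms.append(name)
        elif coeff > 1:
            terms.append(f"{coeff} {name}")
    return " + ".join(terms) if terms else "0"


def _content_lines(text: str):
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if line:
            yield lineno, line


def read_network(text: str) -> ReactionNetwork:
    """Parse a network document into a :class:`ReactionNetwork`.

    Complexes are stored in canonical (lexicographic exponent) order.
    Duplicate reaction lines for the same complex pair are an error, not
    summed.
    """
    lines = list(_content_lines(text))
    if not lines or not lines[0][1].startswith("species"):
        raise NetworkFormatError("document must start with a 'species' line")
    lineno, decl = lines[0]
    species = tuple(decl.split()[1:])
    if not species:
        raise NetworkFormatError("empty species declaration", lineno)
    if len(set(species)) != len(species):
        raise NetworkFormatError("duplicate species label", lineno)

    reactions: dict[tuple[tuple[int, ...], tuple[int, ...]], float] = {}
    order: list[tuple[int, ...]] = []
    for lineno, line in lines[1:]:
        if "->" not in line:
            raise NetworkFormatError("expected 'complex -> complex ; k=<rate>'", lineno)
        head, _, tail = line.partition("->")
        body, _, ratepart = tail.partition(";")
        mt = re.match(r"^\s*k\s*=\s*([-+0-9.eE]+)\s*$", ratepart)
        if not mt:
            raise NetworkFormatError("missing rate annotation 'k=<rate>'", lineno)
        try:
            rate = float(mt.group(1))
        except ValueError:
            raise NetworkFormatError(f"bad rate {mt.group(1)!r}", lineno) from None
        if rate <= 0:
            raise NetworkFormatError(f"nonpositive rate {rate!r}", lineno)
        src = _parse_complex(head, species, lineno)
        tgt = _parse_complex(body, species, lineno)
        if src == tgt:
            raise NetworkFormatError("self-loop reaction", lineno)
        if (src, tgt) in reactions:
            raise NetworkFormatError("duplicate reaction line", lineno)
        reactions[(src, tgt)] = rate
        for c in (src, tgt):
            if c not in order:
                order.append(c)

    columns = sorted(order)  # canonical: lexicographic by exponent vector
    cm = ComplexMatrix(species, np.array(columns, dtype=np.int64).T)
    indexed = {
        (columns.index(src), columns.index(tgt)): k
        for (src, tgt), k in reactions.items()
    }
    return ReactionNetwork(cm, KirchhoffMatrix.from_reactions(len(columns), indexed))


def write_network(net: ReactionNetwork, tol: float = 0.0) -> str:
    """Serialise a network deterministically (canonical complex order)."""
    cm = net.complexes
    cols = [cm.column(j) for j in range(cm.n_complexes)]
    order = sorted(range(len(cols)), key=lambda j: cols[j])
    lines = ["species " + " ".join(cm.species)]
    for src in order:
        for tgt in order:
            if src == tgt:
                continue
            rate = net.kinetics.A[tgt, src]
            if rate > tol:
                lines.append(
                    f"{_format_complex(cols[src], cm.species)} -> "
                    f"{_format_complex(cols[tgt], cm.species)} ; k={rate:.12g}"
                )
    return "\n".join(lines) + "\n"


def read_constraints(text: str, net: ReactionNetwork) -> ConstraintSet:
    """Parse an exclusion list against the complex set of ``net``."""
    cm = net.complexes
    pairs = []
    for lineno, line in _content_lines(text):
        if "->" not in line:
            raise NetworkFormatError("expected 'complex -> complex'", lineno)
        head, _, tail = line.partition("->")
        src = _parse_complex(head, cm.species, lineno)
        tgt = _parse_complex(tail, cm.species, lineno)
        try:
            pairs.append((cm.index_of(src), cm.index_of(tgt)))
        except Exception:
            raise NetworkFormatError(
                "excluded reaction references a complex not in the network", lineno
            ) from None
    return ConstraintSet(pairs, cm.n_complexes)
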