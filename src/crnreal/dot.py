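"""DOT export of reaction graphs.

One node per complex (labelled with its formula), one directed edge per
reaction (labelled with its rate).  When a core report is supplied, core
reactions are drawn solid and non-core reactions dashed.
"""

from __future__ import annotations

from .model import ReactionNetwork
from .realize import CoreReport

__all__ = ["export_reaction_graph"]


def _quote(label: str) -> str:
    return '"' + label.replace("\\", "\\\\").replace('"', '\\"') + '"'


def export_reaction_graph(
    net: ReactionNetwork, annotations: CoreReport | None = None, tol: float = 0.0
) -> str:
    cm = net.complexes
    lines = ["digraph crn {", "  node [shape=box];"]
    for j in range(cm.n_complexes):
        lines.append(f"  c{j} [label={_quote(cm.label(j))}];")
    for src, tgt in net.support(tol):
        rate = net.kinetics.A[tgt, src]
        style = "solid"
        if annotations is not None and (src, tgt) in annotations.non_core:
            style = "dashed"
        lines.append(
            f"  c{src} -> c{tgt} [label={_quote(f'{rate:.6g}')}, style={style}];"
        )
    lines.append("}")
    return "\n".join(lines) + "\n"
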