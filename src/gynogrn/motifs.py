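"""Signed gene-level graphs and feed-forward-loop (FFL) detection.

A Boolean model is collapsed to a signed digraph at gene resolution:
one node per gene, an edge ``u -> v`` with sign ``+1`` for every
positive literal of ``u`` in ``v``'s rule and ``-1`` for every negated
literal.  Transcript/protein node pairs (e.g. the ARR1 transcript and
its phosphorylated protein ARR1P) are merged through the explicit alias
table carried in the model metadata — never by name heuristics — so an
upstream signal acting on the protein form (CK phosphorylating ARR1P)
becomes a positive edge onto the merged gene.  Self-loops (input
identities, intra-gene transcript->protein edges) are dropped: motif
scans exclude them and input-ness is kept as a node attribute instead.

A feed-forward loop is an ordered triple of distinct genes (regulator,
intermediate, target) with the three edges regulator->intermediate,
intermediate->target and regulator->target.  It is *coherent* when the
sign of the direct edge equals the product of the two indirect signs,
and is numbered 1-4 within the coherent and incoherent families by the
standard sign-pattern convention (type 1 = all activating).  Extra
edges (e.g. a reciprocal target->regulator edge) do not disqualify a
triple.

Graphs are ``networkx.DiGraph`` objects with a ``sign`` edge attribute
in ``{+1, -1}``.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .engine import NetworkModel

__all__ = [
    "AmbiguousSignError",
    "FFLMotif",
    "collapse_to_gene_graph",
    "enumerate_ffls",
    "count_coherent_ffls",
    "to_dot",
]


class AmbiguousSignError(ValueError):
    """A regulator appears with both polarities on the same target."""


# (sign regulator->intermediate, intermediate->target, regulator->target)
# -> (coherent?, type number).  Standard four-coherent/four-incoherent
# classification; type 1 coherent is the all-activating wiring.
_FFL_TYPES = {
    (+1, +1, +1): (True, 1),
    (-1, +1, -1): (True, 2),
    (+1, -1, -1): (True, 3),
    (-1, -1, +1): (True, 4),
    (+1, -1, +1): (False, 1),
    (-1, +1, +1): (False, 2),
    (+1, +1, -1): (False, 3),
    (-1, -1, -1): (False, 4),
}


def collapse_to_gene_graph(model: NetworkModel) -> nx.DiGraph:
    """Collapse a Boolean model to a signed gene-level digraph.

    The alias table ``model.metadata["aliases"]`` maps auxiliary node
    names to their gene (e.g. ``{"ARR1P": "ARR1"}``).  A regulator
    appearing both positively and negatively on one (collapsed) target
    is ambiguous and raises :class:`AmbiguousSignError`.
    """
    aliases = dict(model.metadata.get("aliases", {}))
    gene = lambda name: aliases.get(name, name)
    inputs = set(model.inputs)
    g = nx.DiGraph()
    for name in model.nodes:
        gname = gene(name)
        if gname not in g:
            g.add_node(gname, is_input=False)
        if name in inputs:
            g.nodes[gname]["is_input"] = True
    for target in model.nodes:
        tgene = gene(target)
        for source, positive in model.rules[target].literals():
            sgene = gene(source)
            if sgene == tgene:
                continue  # identity input or intra-gene edge
            sign = 1 if positive else -1
            if g.has_edge(sgene, tgene) and g[sgene][tgene]["sign"] != sign:
                raise AmbiguousSignError(
                    f"{sgene} regulates {tgene} with both signs")
            g.add_edge(sgene, tgene, sign=sign)
    return g


@dataclass(frozen=True)
class FFLMotif:
    """One classified feed-forward loop."""

    regulator: str
    intermediate: str
    target: str
    signs: tuple  # (reg->int, int->tgt, reg->tgt), each +1 or -1
    coherent: bool
    ffl_type: int  # 1..4 within the coherent or incoherent family

    @property
    def label(self) -> str:
        family = "coherent" if self.coherent else "incoherent"
        return f"{family} type {self.ffl_type}"


def enumerate_ffls(graph: nx.DiGraph) -> list:
    """All feed-forward loops, lexicographically ordered by node names."""
    motifs = []
    for reg, mid in graph.edges():
        if reg == mid:
            continue
        for tgt in graph.successors(mid):
            if tgt == mid or tgt == reg:
                continue
            if not graph.has_edge(reg, tgt):
                continue
            signs = (graph[reg][mid]["sign"],
                     graph[mid][tgt]["sign"],
                     graph[reg][tgt]["sign"])
            coherent, ffl_type = _FFL_TYPES[signs]
            motifs.append(FFLMotif(reg, mid, tgt, signs, coherent, ffl_type))
    motifs.sort(key=lambda m: (m.regulator, m.intermediate, m.target))
    return motifs


def count_coherent_ffls(graph: nx.DiGraph) -> int:
    """Number of coherent feed-forward loops in ``graph``."""
    return sum(1 for m in enumerate_ffls(graph) if m.coherent)


def to_dot(graph: nx.DiGraph, name: str = "grn") -> str:
    """Render the signed digraph in DOT.

    Activation is drawn with a normal arrowhead, repression with a tee —
    the arrow/T-bar pictorial convention of regulatory-network diagrams.
    """
    lines = [f"digraph {name} {{"]
    for node in sorted(graph.nodes):
        shape = "box" if graph.nodes[node].get("is_input") else "ellipse"
        lines.append(f'  "{node}" [shape={shape}];')
    for u, v in sorted(graph.edges):
        head = "normal" if graph[u][v]["sign"] > 0 else "tee"
        lines.append(f'  "{u}" -> "{v}" [arrowhead={head}];')
    lines.append("}")
    return "\n".join(lines) + "\n"
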