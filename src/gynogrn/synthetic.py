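"""Random Boolean networks and degree-preserving rewirings.

Test machinery for the engine and motif scanner: seeded Kauffman-style
random networks (every generated model is a valid
:class:`~gynogrn.engine.NetworkModel`, so the exhaustive attractor
enumerator can be cross-checked against brute-force simulation on small
``n``), and double-edge-swap rewiring of signed digraphs as a null
model for motif counts.

Determinism is a hard contract: every entry point takes an explicit
seed, draws from a single private ``random.Random`` stream, and equal
inputs produce byte-identical serialized outputs.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx

from .engine import And, Const, Expr, NetworkModel, Not, Or, Var

__all__ = [
    "RULE_CLASSES",
    "GeneratorSpec",
    "random_boolean_network",
    "rewire_preserving_degree",
]

RULE_CLASSES = ("random_truth_table", "AND_of_literals", "OR_of_literals",
                "nested_canalyzing")


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of one random-network draw.

    ``in_degree`` is either a single k applied to every node or one
    value per node.  ``negation_probability`` is the chance each parent
    literal is negated (ignored by ``random_truth_table``, whose random
    output column already spans all polarities).  The seed is mandatory:
    there is no implicit entropy.
    """

    n_nodes: int
    in_degree: int | Sequence[int] = 2
    rule_class: str = "random_truth_table"
    negation_probability: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 1:
            raise ValueError("n_nodes must be >= 1")
        if self.rule_class not in RULE_CLASSES:
            raise ValueError(f"unknown rule_class {self.rule_class!r}; "
                             f"expected one of {RULE_CLASSES}")
        if not 0.0 <= self.negation_probability <= 1.0:
            raise ValueError("negation_probability must lie in [0, 1]")
        if not isinstance(self.seed, int):
            raise ValueError("seed must be an integer (it is mandatory)")
        for k in self.degrees():
            if not 0 <= k < self.n_nodes:
                raise ValueError(
                    f"in-degree {k} infeasible for {self.n_nodes} nodes "
                    f"(parents are sampled without replacement, no "
                    f"self-edges)")

    def degrees(self) -> tuple:
        if isinstance(self.in_degree, int):
            return (self.in_degree,) * self.n_nodes
        degs = tuple(self.in_degree)
        if len(degs) != self.n_nodes:
            raise ValueError("per-node in_degree must have n_nodes entries")
        return degs


def _literal(name: str, rng: random.Random, p_neg: float) -> Expr:
    lit = Var(name)
    return Not(lit) if rng.random() < p_neg else lit


def _truth_table_rule(parents: Sequence[str], rng: random.Random) -> Expr:
    """A uniformly random Boolean function over ``parents``, in DNF."""
    k = len(parents)
    outputs = [rng.randrange(2) for _ in range(2 ** k)]
    if not any(outputs):
        return Const(0)
    if all(outputs):
        return Const(1)
    minterms = []
    for row, out in enumerate(outputs):
        if not out:
            continue
        lits = []
        for i, parent in enumerate(parents):
            bit = (row >> (k - 1 - i)) & 1
            lits.append(Var(parent) if bit else Not(Var(parent)))
        minterms.append(lits[0] if len(lits) == 1 else And(tuple(lits)))
    return minterms[0] if len(minterms) == 1 else Or(tuple(minterms))


def _nested_canalyzing_rule(parents: Sequence[str], rng: random.Random,
                            p_neg: float) -> Expr:
    """A nested canalyzing function: each literal in turn can fix the
    output, innermost literal decides the rest."""
    expr = _literal(parents[-1], rng, p_neg)
    for name in reversed(parents[:-1]):
        op = And if rng.randrange(2) else Or
        expr = op((_literal(name, rng, p_neg), expr))
    return expr


def random_boolean_network(spec: GeneratorSpec) -> NetworkModel:
    """Draw one random Boolean network; equal specs give equal models.

    Parents are sampled without replacement from the other nodes (no
    self-edges).  Zero-parent nodes get a random constant rule.
    """
    rng = random.Random(spec.seed)
    names = [f"N{i}" for i in range(spec.n_nodes)]
    rules = {}
    for name, k in zip(names, spec.degrees()):
        if k == 0:
            rules[name] = Const(rng.randrange(2))
            continue
        parents = rng.sample([p for p in names if p != name], k)
        if spec.rule_class == "random_truth_table":
            rules[name] = _truth_table_rule(parents, rng)
        elif spec.rule_class == "AND_of_literals":
            lits = tuple(_literal(p, rng, spec.negation_probability)
                         for p in parents)
            rules[name] = lits[0] if len(lits) == 1 else And(lits)
        elif spec.rule_class == "OR_of_literals":
            lits = tuple(_literal(p, rng, spec.negation_probability)
                         for p in parents)
            rules[name] = lits[0] if len(lits) == 1 else Or(lits)
        else:  # nested_canalyzing
            rules[name] = _nested_canalyzing_rule(
                parents, rng, spec.negation_probability)
    metadata = {"generator": {
        "n_nodes": spec.n_nodes,
        "in_degree": list(spec.degrees()),
        "rule_class": spec.rule_class,
        "negation_probability": spec.negation_probability,
        "seed": spec.seed,
    }}
    return NetworkModel(names, rules, metadata)


def rewire_preserving_degree(graph: nx.DiGraph, n_swaps: int, seed: int,
                             max_attempts_per_swap: int = 100
                             ) -> nx.DiGraph:
    """Randomize a signed digraph by double-edge swaps.

    Each swap replaces edges ``(a, b)`` and ``(c, d)`` with ``(a, d)``
    and ``(c, b)``; candidates creating self-loops or duplicating an
    existing edge are rejected, so in- and out-degree sequences are
    preserved exactly and every edge keeps its sign (the sign travels
    with the source-anchored half of the swap).  When no valid swap is
    found within the attempt budget the graph accumulated so far is
    returned and the shortfall is recorded in
    ``graph.graph["unperformed_swaps"]`` with a warning.
    """
    if graph.number_of_edges() < 2:
        raise ValueError("rewiring needs a graph with at least 2 edges")
    rng = random.Random(seed)
    g = graph.copy()
    g.graph["unperformed_swaps"] = 0
    edges = list(g.edges())
    performed = 0
    while performed < n_swaps:
        for _ in range(max_attempts_per_swap):
            i, j = rng.sample(range(len(edges)), 2)
            a, b = edges[i]
            c, d = edges[j]
            if a == d or c == b:
                continue
            if (a, d) == (c, b) or g.has_edge(a, d) or g.has_edge(c, b):
                continue
            sign_ab = g[a][b]["sign"]
            sign_cd = g[c][d]["sign"]
            g.remove_edge(a, b)
            g.remove_edge(c, d)
            g.add_edge(a, d, sign=sign_ab)
            g.add_edge(c, b, sign=sign_cd)
            edges[i] = (a, d)
            edges[j] = (c, b)
            break
        else:
            shortfall = n_swaps - performed
            g.graph["unperformed_swaps"] = shortfall
            warnings.warn(
                f"no valid swap found after {max_attempts_per_swap} "
                f"attempts; {shortfall} of {n_swaps} swaps not performed",
                stacklevel=2)
            return g
        performed += 1
    return g
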