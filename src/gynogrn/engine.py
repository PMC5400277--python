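"""Synchronous Boolean network engine.

A Boolean network assigns every node a binary activity value and a logic
rule over the current values of its regulators.  Under the synchronous
(parallel) update scheme all nodes are recomputed simultaneously, so the
dynamics form a deterministic map on a finite state space of ``2**n``
states.  Every trajectory therefore eventually revisits a state and
enters a cycle; a length-1 cycle is a *fixed point* (a steady expression
pattern).  This module provides:

* an expression tree for rules (:class:`Var`, :class:`Not`, :class:`And`,
  :class:`Or`, :class:`Const`),
* the :class:`NetworkModel` container (ordered nodes, one rule each),
* rule evaluation and synchronous stepping,
* trajectory simulation with explicit truncation flagging,
* exhaustive fixed-point and attractor enumeration with basin sizes,
* node clamping, the in silico analogue of a knockout (clamp to 0) or a
  constitutive-expression line (clamp to 1).

States are plain tuples of 0/1 in declared node order; the bitstring
encoding puts the first declared node in the most significant position,
so lexicographic order on bitstrings coincides with integer order.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

__all__ = [
    "ModelValidationError",
    "StateSpaceTooLargeError",
    "MAX_EXHAUSTIVE_NODES",
    "Expr",
    "Const",
    "Var",
    "Not",
    "And",
    "Or",
    "NetworkModel",
    "State",
    "Trajectory",
    "Attractor",
    "evaluate_rule",
    "synchronous_step",
    "simulate",
    "fixed_points",
    "enumerate_attractors",
    "clamp",
    "relabel",
    "state_to_bitstring",
    "bitstring_to_state",
    "code_to_state",
    "state_to_code",
]

#: Hard ceiling for exhaustive state-space sweeps (2**24 successor
#: evaluations is the desk-scale limit; beyond it the engine refuses
#: rather than silently grinding).
MAX_EXHAUSTIVE_NODES = 24

State = tuple  # alias for readability: a tuple of 0/1 in node order


class ModelValidationError(ValueError):
    """A model references undeclared nodes or is otherwise malformed."""


class StateSpaceTooLargeError(ValueError):
    """Exhaustive enumeration was requested above the node-count cap."""


# ---------------------------------------------------------------------------
# Rule expressions
# ---------------------------------------------------------------------------

class Expr:
    """Base class for Boolean rule expressions.

    Expressions are immutable trees; evaluation on a complete assignment
    is total, deterministic and side-effect free.
    """

    def evaluate(self, env: Mapping[str, int]) -> int:
        raise NotImplementedError

    def variables(self) -> frozenset:
        return frozenset(name for name, _ in self.literals())

    def literals(self) -> Iterator[tuple[str, bool]]:
        """Yield ``(name, positive)`` pairs; polarity flips under NOT."""
        yield from self._literals(True)

    def _literals(self, positive: bool) -> Iterator[tuple[str, bool]]:
        raise NotImplementedError


@dataclass(frozen=True)
class Const(Expr):
    value: int

    def __post_init__(self):
        if self.value not in (0, 1):
            raise ValueError(f"constant must be 0 or 1, got {self.value!r}")

    def evaluate(self, env):
        return self.value

    def _literals(self, positive):
        return iter(())


@dataclass(frozen=True)
class Var(Expr):
    name: str

    def evaluate(self, env):
        return env[self.name]

    def _literals(self, positive):
        yield (self.name, positive)


@dataclass(frozen=True)
class Not(Expr):
    operand: Expr

    def evaluate(self, env):
        return 1 - self.operand.evaluate(env)

    def _literals(self, positive):
        yield from self.operand._literals(not positive)


@dataclass(frozen=True)
class And(Expr):
    operands: tuple

    def __init__(self, *operands):
        # accept And(a, b) or And((a, b)) for convenience
        if len(operands) == 1 and isinstance(operands[0], (tuple, list)):
            operands = tuple(operands[0])
        if not operands:
            raise ValueError("AND requires at least one operand")
        object.__setattr__(self, "operands", tuple(operands))

    def evaluate(self, env):
        for op in self.operands:
            if not op.evaluate(env):
                return 0
        return 1

    def _literals(self, positive):
        for op in self.operands:
            yield from op._literals(positive)


@dataclass(frozen=True)
class Or(Expr):
    operands: tuple

    def __init__(self, *operands):
        if len(operands) == 1 and isinstance(operands[0], (tuple, list)):
            operands = tuple(operands[0])
        if not operands:
            raise ValueError("OR requires at least one operand")
        object.__setattr__(self, "operands", tuple(operands))

    def evaluate(self, env):
        for op in self.operands:
            if op.evaluate(env):
                return 1
        return 0

    def _literals(self, positive):
        for op in self.operands:
            yield from op._literals(positive)


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

class NetworkModel:
    """An ordered Boolean network: nodes, one rule per node, metadata.

    Node order is fixed at construction and defines the state encoding
    (first node = most significant bit).  *Input* nodes are those whose
    rule is the identity on themselves; they hold whatever value the
    initial state (or a clamp) gives them.

    Parameters
    ----------
    nodes:
        Ordered node names; unique, non-empty, case-sensitive.
    rules:
        Mapping from node name to :class:`Expr`; must cover exactly the
        declared nodes, and every literal must reference a declared node.
    metadata:
        Free-form provenance dict.  The key ``"aliases"`` (mapping node
        name -> gene name) drives transcript/protein collapsing in
        :mod:`gynogrn.motifs`.
    """

    def __init__(self, nodes: Sequence[str], rules: Mapping[str, Expr],
                 metadata: Mapping | None = None):
        self.nodes = tuple(nodes)
        self.rules = dict(rules)
        self.metadata = dict(metadata or {})
        self._index = {name: i for i, name in enumerate(self.nodes)}
        self._validate()

    def _validate(self) -> None:
        if not self.nodes:
            raise ModelValidationError("model has no nodes")
        if len(self._index) != len(self.nodes):
            raise ModelValidationError("duplicate node names")
        for name in self.nodes:
            if not name or not isinstance(name, str):
                raise ModelValidationError(f"invalid node name {name!r}")
        if set(self.rules) != set(self.nodes):
            missing = set(self.nodes) - set(self.rules)
            extra = set(self.rules) - set(self.nodes)
            raise ModelValidationError(
                f"rules do not match nodes (missing {sorted(missing)}, "
                f"extra {sorted(extra)})")
        declared = set(self.nodes)
        for name, rule in self.rules.items():
            unknown = rule.variables() - declared
            if unknown:
                raise ModelValidationError(
                    f"rule for {name!r} references undeclared node(s) "
                    f"{sorted(unknown)}")

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def inputs(self) -> tuple:
        """Nodes whose rule is the identity on themselves."""
        return tuple(name for name in self.nodes
                     if self.rules[name] == Var(name))

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise ModelValidationError(f"unknown node {name!r}") from None

    def state_from_mapping(self, values: Mapping[str, int],
                           default: int = 0) -> State:
        """Build a state tuple from a partial name->bit mapping."""
        unknown = set(values) - set(self.nodes)
        if unknown:
            raise ModelValidationError(f"unknown node(s) {sorted(unknown)}")
        return tuple(values.get(name, default) for name in self.nodes)

    def __eq__(self, other):
        return (isinstance(other, NetworkModel)
                and self.nodes == other.nodes and self.rules == other.rules)

    def __repr__(self):
        return f"NetworkModel({len(self.nodes)} nodes: {', '.join(self.nodes)})"


# ---------------------------------------------------------------------------
# State encoding helpers
# ---------------------------------------------------------------------------

def state_to_bitstring(state: State) -> str:
    return "".join(str(b) for b in state)


def bitstring_to_state(bits: str) -> State:
    if not bits or any(c not in "01" for c in bits):
        raise ValueError(f"not a bitstring: {bits!r}")
    return tuple(int(c) for c in bits)


def state_to_code(state: State) -> int:
    code = 0
    for b in state:
        code = (code << 1) | b
    return code


def code_to_state(code: int, n: int) -> State:
    return tuple((code >> (n - 1 - i)) & 1 for i in range(n))


def _check_state(model: NetworkModel, state: State) -> None:
    if len(state) != model.n:
        raise ModelValidationError(
            f"state length {len(state)} != model size {model.n}")
    if any(b not in (0, 1) for b in state):
        raise ModelValidationError(f"state is not binary: {state!r}")


def _check_cap(model: NetworkModel) -> None:
    if model.n > MAX_EXHAUSTIVE_NODES:
        raise StateSpaceTooLargeError(
            f"exhaustive enumeration refused for {model.n} nodes "
            f"(cap {MAX_EXHAUSTIVE_NODES}: 2**{model.n} states)")


# ---------------------------------------------------------------------------
# Dynamics
# ---------------------------------------------------------------------------

def evaluate_rule(rule: Expr, state: State, model: NetworkModel) -> int:
    """Evaluate one rule on a complete state of ``model``; pure."""
    _check_state(model, state)
    return rule.evaluate(dict(zip(model.nodes, state)))


def synchronous_step(model: NetworkModel, state: State) -> State:
    """Apply one synchronous (parallel) update to ``state``.

    All nodes simultaneously take the value of their rule evaluated on
    the *input* state; input nodes (identity rules) keep their value.
    """
    _check_state(model, state)
    env = dict(zip(model.nodes, state))
    return tuple(model.rules[name].evaluate(env) for name in model.nodes)


@dataclass
class Trajectory:
    """A synchronous time course from one initial condition.

    ``states`` lists the distinct states visited in order; ``terminal``
    is the index at which the attractor is entered (the first state that
    the dynamics revisit), or ``None`` when the run was truncated before
    any revisit.  The cycle itself is ``states[terminal:]``.
    """

    states: list
    terminal: int | None
    truncated: bool = False

    @property
    def attractor_states(self) -> list:
        if self.terminal is None:
            raise ValueError("trajectory was truncated before reaching "
                             "an attractor")
        return self.states[self.terminal:]

    def __len__(self):
        return len(self.states)


def simulate(model: NetworkModel, initial: State,
             max_steps: int | None = None) -> Trajectory:
    """Iterate synchronous updates until a state is revisited.

    ``max_steps`` bounds the number of *distinct* states recorded; the
    default ``2**n`` guarantees attractor entry.  A smaller bound may
    truncate the run, which is flagged (``truncated=True``), never
    silent.
    """
    _check_state(model, initial)
    if max_steps is None:
        max_steps = 2 ** model.n
    if max_steps < 1:
        raise ValueError("max_steps must be >= 1")
    states = [tuple(initial)]
    seen = {tuple(initial): 0}
    while True:
        nxt = synchronous_step(model, states[-1])
        if nxt in seen:
            return Trajectory(states=states, terminal=seen[nxt])
        if len(states) >= max_steps:
            return Trajectory(states=states, terminal=None, truncated=True)
        seen[nxt] = len(states)
        states.append(nxt)


def fixed_points(model: NetworkModel) -> list:
    """All states mapped to themselves, sorted by bitstring."""
    _check_cap(model)
    n = model.n
    out = []
    for code in range(2 ** n):
        state = code_to_state(code, n)
        if synchronous_step(model, state) == state:
            out.append(state)
    return out  # ascending code order == lexicographic bitstring order


@dataclass(frozen=True)
class Attractor:
    """A terminal cycle of the synchronous dynamics.

    ``states`` is rotated so the lexicographically smallest bitstring
    comes first (canonical form); ``basin_size`` counts every state
    whose trajectory reaches this cycle, the cycle itself included.
    """

    states: tuple
    kind: str  # "fixed_point" | "cycle"
    basin_size: int

    @property
    def is_fixed_point(self) -> bool:
        return self.kind == "fixed_point"

    @property
    def representative(self) -> State:
        return self.states[0]

    def __len__(self):
        return len(self.states)


def _successor_table(model: NetworkModel) -> list:
    n = model.n
    rules = [model.rules[name] for name in model.nodes]
    nodes = model.nodes
    table = []
    for code in range(2 ** n):
        state = code_to_state(code, n)
        env = dict(zip(nodes, state))
        nxt = 0
        for rule in rules:
            nxt = (nxt << 1) | rule.evaluate(env)
        table.append(nxt)
    return table


def enumerate_attractors(model: NetworkModel) -> list:
    """Exhaustively enumerate all attractors and their basin sizes.

    Builds the full state-transition graph over ``2**n`` states, finds
    every terminal cycle and assigns each state to the unique attractor
    its trajectory reaches, so basins partition the state space.
    Attractors are canonicalized (smallest bitstring first) and sorted
    by their representative state.
    """
    _check_cap(model)
    n = model.n
    succ = _successor_table(model)
    size = 2 ** n
    attr_of = [-1] * size
    cycles: list = []
    for start in range(size):
        if attr_of[start] != -1:
            continue
        path: list = []
        pos: dict = {}
        x = start
        while attr_of[x] == -1 and x not in pos:
            pos[x] = len(path)
            path.append(x)
            x = succ[x]
        if x in pos:  # closed a new cycle on this path
            cyc = path[pos[x]:]
            aid = len(cycles)
            cycles.append(cyc)
        else:
            aid = attr_of[x]
        for y in path:
            attr_of[y] = aid
    basin = Counter(attr_of)
    attractors = []
    for aid, cyc in enumerate(cycles):
        k = cyc.index(min(cyc))
        canon = cyc[k:] + cyc[:k]
        attractors.append(Attractor(
            states=tuple(code_to_state(c, n) for c in canon),
            kind="fixed_point" if len(canon) == 1 else "cycle",
            basin_size=basin[aid],
        ))
    attractors.sort(key=lambda a: a.representative)
    return attractors


# ---------------------------------------------------------------------------
# Perturbation and relabeling
# ---------------------------------------------------------------------------

def clamp(model: NetworkModel, node: str, value: int) -> NetworkModel:
    """Return a copy of ``model`` with ``node`` held constant at ``value``.

    Clamping to 0 emulates a knockout, to 1 a constitutive-expression
    line.  The original model is unchanged; all other rules are reused
    verbatim.
    """
    if node not in model.rules:
        raise ModelValidationError(f"cannot clamp unknown node {node!r}")
    if value not in (0, 1):
        raise ValueError(f"clamp value must be 0 or 1, got {value!r}")
    rules = dict(model.rules)
    rules[node] = Const(value)
    metadata = dict(model.metadata)
    metadata.setdefault("clamps", [])
    metadata["clamps"] = list(metadata["clamps"]) + [(node, value)]
    return NetworkModel(model.nodes, rules, metadata)


def _rename_expr(expr: Expr, mapping: Mapping[str, str]) -> Expr:
    if isinstance(expr, Const):
        return expr
    if isinstance(expr, Var):
        return Var(mapping.get(expr.name, expr.name))
    if isinstance(expr, Not):
        return Not(_rename_expr(expr.operand, mapping))
    if isinstance(expr, And):
        return And(tuple(_rename_expr(o, mapping) for o in expr.operands))
    if isinstance(expr, Or):
        return Or(tuple(_rename_expr(o, mapping) for o in expr.operands))
    raise TypeError(f"unknown expression type {type(expr)!r}")


def relabel(model: NetworkModel, mapping: Mapping[str, str]) -> NetworkModel:
    """Consistently rename nodes; the state-transition graph is isomorphic."""
    new_nodes = [mapping.get(name, name) for name in model.nodes]
    new_rules = {mapping.get(name, name): _rename_expr(rule, mapping)
                 for name, rule in model.rules.items()}
    return NetworkModel(new_nodes, new_rules, dict(model.metadata))
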