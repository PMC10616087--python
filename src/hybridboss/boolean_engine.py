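"""Continuous-time stochastic simulation of Boolean networks.

Each node of a Boolean network carries a logic expression plus two flip-rate
expressions (``rate_up`` for 0->1, ``rate_down`` for 1->0) evaluated in the
current network state.  The network is simulated as a continuous-time Markov
chain with the Gillespie algorithm: exactly one node flips per event, after
an exponential waiting time set by the total propensity.  Ensembles of
trajectories estimate per-node activation probabilities over time, optionally
mixing sub-populations with different forced-node (mutant) sets.

Networks are read from and written to a restricted text dialect::

    node NAME {
      logic = A AND NOT B;
      rate_up = @logic ? $k : 0;
      rate_down = @logic ? 0 : 1;
    }

with a companion configuration dialect for parameters and initial-state
probabilities (``$k = 2.5;``, ``A.istate = 1;``, ``A.is_internal = FALSE;``).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ParseError",
    "Expression",
    "NodeSpec",
    "BooleanNetwork",
    "NetworkState",
    "EngineSettings",
    "MutantSpec",
    "InitialCondition",
    "parse_network",
    "parse_bnd",
    "parse_cfg",
    "serialize_network",
    "evaluate_logic",
    "propensities",
    "gillespie_step",
    "run_interval",
    "ensemble_run",
]


class ParseError(ValueError):
    """Raised for malformed network or configuration text."""


# ---------------------------------------------------------------------------
# Expression mini-language
# ---------------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<num>\d+\.?\d*(?:[eE][+-]?\d+)?|\.\d+(?:[eE][+-]?\d+)?)"
    r"|(?P<param>\$[A-Za-z_]\w*)"
    r"|(?P<logic>@logic)"
    r"|(?P<name>[A-Za-z_]\w*)"
    r"|(?P<op>\|\||&&|[()?:!+\-*/]))"
)

_KEYWORDS = {"AND": "&&", "OR": "||", "NOT": "!", "and": "&&", "or": "||", "not": "!"}


def _tokenize(text: str, line: int) -> list[tuple[str, str]]:
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise ParseError(f"line {line}: cannot tokenize {text[pos:]!r}")
        pos = m.end()
        if m.lastgroup == "name" and m.group("name") in _KEYWORDS:
            tokens.append(("op", _KEYWORDS[m.group("name")]))
        else:
            tokens.append((m.lastgroup, m.group(m.lastgroup)))
    tokens.append(("end", ""))
    return tokens


@dataclass(frozen=True)
class Expression:
    """A parsed logic/rate expression.

    Holds the source text and an AST; compiles to a plain Python function of
    ``(bits, params, logic_value)`` for fast repeated evaluation.
    """

    source: str
    ast: tuple
    identifiers: frozenset[str]
    parameters: frozenset[str]
    uses_logic: bool

    @classmethod
    def parse(cls, text: str, line: int = 0) -> "Expression":
        tokens = _tokenize(text, line)
        parser = _ExprParser(tokens, line)
        ast = parser.ternary()
        parser.expect("end")
        names: set[str] = set()
        params: set[str] = set()
        uses_logic = [False]

        def walk(node: tuple) -> None:
            kind = node[0]
            if kind == "name":
                names.add(node[1])
            elif kind == "param":
                params.add(node[1])
            elif kind == "logic":
                uses_logic[0] = True
            else:
                for child in node[1:]:
                    if isinstance(child, tuple):
                        walk(child)

        walk(ast)
        return cls(text.strip(), ast, frozenset(names), frozenset(params), uses_logic[0])

    def compile(self, index: Mapping[str, int]) -> Callable:
        """Compile to ``f(bits, params, logic) -> float`` with node-name lookups
        resolved to integer indices at compile time."""
        src = _codegen(self.ast, index)
        code = compile(src, f"<expr:{self.source}>", "eval")
        return lambda bits, params, logic=0.0: eval(  # noqa: S307 - trusted codegen
            code, {"__builtins__": {}}, {"b": bits, "p": params, "L": logic}
        )

    def evaluate(self, bits: Mapping[str, float] | np.ndarray, index: Mapping[str, int],
                 params: Mapping[str, float], logic: float = 0.0) -> float:
        return self.compile(index)(bits, params, logic)


def _codegen(node: tuple, index: Mapping[str, int]) -> str:
    kind = node[0]
    if kind == "num":
        return repr(node[1])
    if kind == "name":
        return f"b[{index[node[1]]}]"
    if kind == "param":
        return f"p[{node[1]!r}]"
    if kind == "logic":
        return "L"
    if kind == "not":
        return f"(0.0 if ({_codegen(node[1], index)}) else 1.0)"
    if kind == "and":
        return f"(1.0 if (({_codegen(node[1], index)}) and ({_codegen(node[2], index)})) else 0.0)"
    if kind == "or":
        return f"(1.0 if (({_codegen(node[1], index)}) or ({_codegen(node[2], index)})) else 0.0)"
    if kind == "ternary":
        return (f"(({_codegen(node[2], index)}) if ({_codegen(node[1], index)})"
                f" else ({_codegen(node[3], index)}))")
    if kind in ("+", "-", "*", "/"):
        return f"(({_codegen(node[1], index)}) {kind} ({_codegen(node[2], index)}))"
    if kind == "neg":
        return f"(-({_codegen(node[1], index)}))"
    raise AssertionError(f"unknown AST node {kind}")


class _ExprParser:
    """Recursive-descent parser.  Precedence (low to high):
    ternary, OR, AND, NOT, additive, multiplicative, unary minus, atom."""

    def __init__(self, tokens: list[tuple[str, str]], line: int):
        self.tokens = tokens
        self.pos = 0
        self.line = line

    def peek(self) -> tuple[str, str]:
        return self.tokens[self.pos]

    def next(self) -> tuple[str, str]:
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def expect(self, kind: str, value: str | None = None) -> None:
        tok = self.next()
        if tok[0] != kind or (value is not None and tok[1] != value):
            raise ParseError(f"line {self.line}: expected {value or kind}, got {tok[1]!r}")

    def ternary(self) -> tuple:
        cond = self.or_expr()
        if self.peek() == ("op", "?"):
            self.next()
            then = self.ternary()
            self.expect("op", ":")
            other = self.ternary()
            return ("ternary", cond, then, other)
        return cond

    def or_expr(self) -> tuple:
        left = self.and_expr()
        while self.peek() == ("op", "||"):
            self.next()
            left = ("or", left, self.and_expr())
        return left

    def and_expr(self) -> tuple:
        left = self.not_expr()
        while self.peek() == ("op", "&&"):
            self.next()
            left = ("and", left, self.not_expr())
        return left

    def not_expr(self) -> tuple:
        if self.peek() == ("op", "!"):
            self.next()
            return ("not", self.not_expr())
        return self.additive()

    def additive(self) -> tuple:
        left = self.multiplicative()
        while self.peek() in (("op", "+"), ("op", "-")):
            op = self.next()[1]
            left = (op, left, self.multiplicative())
        return left

    def multiplicative(self) -> tuple:
        left = self.unary()
        while self.peek() in (("op", "*"), ("op", "/")):
            op = self.next()[1]
            left = (op, left, self.unary())
        return left

    def unary(self) -> tuple:
        if self.peek() == ("op", "-"):
            self.next()
            return ("neg", self.unary())
        return self.atom()

    def atom(self) -> tuple:
        kind, value = self.next()
        if kind == "num":
            return ("num", float(value))
        if kind == "param":
            return ("param", value[1:])
        if kind == "logic":
            return ("logic",)
        if kind == "name":
            return ("name", value)
        if (kind, value) == ("op", "("):
            inner = self.ternary()
            self.expect("op", ")")
            return inner
        raise ParseError(f"line {self.line}: unexpected token {value!r}")


_ZERO = Expression.parse("0")


def _is_constant_zero(expr: Expression) -> bool:
    return expr.ast == ("num", 0.0)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class NodeSpec:
    """One Boolean node: logic plus 0->1 and 1->0 flip-rate expressions
    (rates in 1/Boolean-time)."""

    name: str
    logic: Expression
    rate_up: Expression
    rate_down: Expression
    is_internal: bool = True


@dataclass(frozen=True)
class MutantSpec:
    """A node forced to a fixed value for the whole simulation."""

    node: str
    forced_value: bool


@dataclass
class InitialCondition:
    """Per-node probability of starting ON; unlisted nodes default to 0.5."""

    probabilities: dict[str, float] = field(default_factory=dict)
    default: float = 0.5

    def probability(self, node: str) -> float:
        return self.probabilities.get(node, self.default)

    def sample(self, network: "BooleanNetwork", rng: np.random.Generator) -> np.ndarray:
        probs = np.array([self.probability(n.name) for n in network.nodes])
        return (rng.random(len(probs)) < probs).astype(np.float64)


class BooleanNetwork:
    """A Boolean network: ordered nodes, shared parameters, input/output roles.

    Input nodes are nodes whose flip rates are both the constant 0 (they are
    held between external updates); output nodes are those declared
    ``is_internal = FALSE``.
    """

    def __init__(self, nodes: Sequence[NodeSpec], parameters: Mapping[str, float] | None = None,
                 input_nodes: Iterable[str] | None = None,
                 output_nodes: Iterable[str] | None = None):
        names = [n.name for n in nodes]
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise ParseError(f"duplicate node declaration: {sorted(dupes)}")
        self.nodes: list[NodeSpec] = list(nodes)
        self.parameters: dict[str, float] = dict(parameters or {})
        self.index: dict[str, int] = {n: i for i, n in enumerate(names)}
        self._check_identifiers()
        if input_nodes is None:
            input_nodes = [n.name for n in self.nodes
                           if _is_constant_zero(n.rate_up) and _is_constant_zero(n.rate_down)]
        if output_nodes is None:
            output_nodes = [n.name for n in self.nodes if not n.is_internal]
        self.input_nodes: list[str] = list(input_nodes)
        self.output_nodes: list[str] = list(output_nodes)
        for group in (self.input_nodes, self.output_nodes):
            for name in group:
                if name not in self.index:
                    raise ParseError(f"input/output role references unknown node {name!r}")
        self._compiled: list[tuple[Callable, Callable, Callable]] | None = None

    # -- validation ---------------------------------------------------------
    def _check_identifiers(self) -> None:
        declared = set(self.index)
        for spec in self.nodes:
            for expr, what in ((spec.logic, "logic"), (spec.rate_up, "rate_up"),
                               (spec.rate_down, "rate_down")):
                free = expr.identifiers - declared
                if free:
                    raise ParseError(
                        f"node {spec.name}: undeclared identifier {sorted(free)} in {what}")
                missing = expr.parameters - set(self.parameters)
                for p in missing:
                    # parameters may be supplied later via CFG; register with NaN
                    self.parameters.setdefault(p, math.nan)
                if expr.uses_logic and what == "logic":
                    raise ParseError(f"node {spec.name}: @logic is not allowed inside logic")

    # -- compilation --------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def compiled(self) -> list[tuple[Callable, Callable, Callable]]:
        if self._compiled is None:
            self._compiled = [
                (n.logic.compile(self.index), n.rate_up.compile(self.index),
                 n.rate_down.compile(self.index))
                for n in self.nodes
            ]
        return self._compiled

    def set_parameter(self, name: str, value: float) -> None:
        self.parameters[name] = float(value)

    def node(self, name: str) -> NodeSpec:
        return self.nodes[self.index[name]]


@dataclass
class NetworkState:
    """Bit vector plus elapsed Boolean time for one trajectory."""

    bits: np.ndarray
    boolean_time: float = 0.0

    def copy(self) -> "NetworkState":
        return NetworkState(self.bits.copy(), self.boolean_time)

    def value(self, network: BooleanNetwork, node: str) -> bool:
        return bool(self.bits[network.index[node]])


@dataclass
class EngineSettings:
    """Timing of the intracellular clock relative to simulation minutes.

    ``time_step`` is the wall interval (minutes) between regulatory updates;
    each update advances the Boolean clock by ``time_step / scaling`` units;
    ``time_stochasticity`` sigma > 0 lognormally jitters the wall interval
    (mean preserved).
    """

    time_step: float = 12.0
    scaling: float = 1.0
    time_stochasticity: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.time_step <= 0:
            raise ValueError("time_step must be > 0")
        if self.scaling <= 0:
            raise ValueError("scaling must be > 0")
        if self.time_stochasticity < 0:
            raise ValueError("time_stochasticity must be >= 0")

    def boolean_interval(self) -> float:
        return self.time_step / self.scaling

    def next_wall_interval(self, rng: np.random.Generator) -> float:
        sigma = self.time_stochasticity
        if sigma == 0:
            return self.time_step
        z = rng.standard_normal()
        return self.time_step * math.exp(sigma * z - 0.5 * sigma * sigma)


# ---------------------------------------------------------------------------
# Parsing the restricted BND / CFG dialect
# ---------------------------------------------------------------------------

_NODE_BLOCK_RE = re.compile(r"node\s+([A-Za-z_]\w*)\s*\{([^}]*)\}", re.S)


def _strip_comments(text: str) -> str:
    return re.sub(r"//[^\n]*", "", text)


def parse_bnd(bnd_text: str) -> BooleanNetwork:
    """Parse the restricted BND dialect into a :class:`BooleanNetwork`."""
    clean = _strip_comments(bnd_text)
    nodes: list[NodeSpec] = []
    consumed = 0
    for m in _NODE_BLOCK_RE.finditer(clean):
        line = clean.count("\n", 0, m.start()) + 1
        name, body = m.group(1), m.group(2)
        fields: dict[str, Expression] = {}
        for stmt in body.split(";"):
            stmt = stmt.strip()
            if not stmt:
                continue
            if "=" not in stmt:
                raise ParseError(f"line {line}: malformed statement {stmt!r} in node {name}")
            key, _, rhs = stmt.partition("=")
            key = key.strip()
            if key not in ("logic", "rate_up", "rate_down"):
                raise ParseError(f"line {line}: unknown field {key!r} in node {name}")
            fields[key] = Expression.parse(rhs.strip(), line)
        if "logic" not in fields:
            raise ParseError(f"line {line}: node {name} lacks a logic field")
        rate_up = fields.get("rate_up", _ZERO)
        rate_down = fields.get("rate_down", _ZERO)
        for what in ("rate_up", "rate_down"):
            expr = fields.get(what)
            if expr is not None and expr.ast[0] == "num" and expr.ast[1] < 0:
                raise ParseError(f"line {line}: node {name}: negative literal rate in {what}")
            if expr is not None and expr.ast[0] == "neg":
                raise ParseError(f"line {line}: node {name}: negative literal rate in {what}")
        nodes.append(NodeSpec(name, fields["logic"], rate_up, rate_down))
        consumed += 1
    if consumed == 0:
        raise ParseError("no node blocks found in BND text")
    leftover = _NODE_BLOCK_RE.sub("", clean).strip()
    if leftover:
        first = leftover.splitlines()[0].strip()
        raise ParseError(f"unparsed BND content near {first!r}")
    return BooleanNetwork(nodes)


_CFG_PARAM_RE = re.compile(r"^\$([A-Za-z_]\w*)\s*=\s*([-\d.eE+]+)$")
_CFG_ISTATE_RE = re.compile(r"^([A-Za-z_]\w*)\.istate\s*=\s*(.+)$")
_CFG_INTERNAL_RE = re.compile(r"^([A-Za-z_]\w*)\.is_internal\s*=\s*(TRUE|FALSE)$", re.I)


def parse_cfg(cfg_text: str, network: BooleanNetwork) -> InitialCondition:
    """Apply the restricted CFG dialect: parameter overrides, initial-state
    probabilities, internal/output flags.  Mutates ``network`` in place and
    returns the initial condition."""
    init = InitialCondition()
    for lineno, raw in enumerate(_strip_comments(cfg_text).split("\n"), start=1):
        for stmt in raw.split(";"):
            stmt = stmt.strip()
            if not stmt:
                continue
            m = _CFG_PARAM_RE.match(stmt)
            if m:
                network.set_parameter(m.group(1), float(m.group(2)))
                continue
            m = _CFG_ISTATE_RE.match(stmt)
            if m:
                name, rhs = m.group(1), m.group(2).strip()
                if name not in network.index:
                    raise ParseError(f"line {lineno}: istate for undeclared node {name!r}")
                init.probabilities[name] = _parse_istate(rhs, lineno)
                continue
            m = _CFG_INTERNAL_RE.match(stmt)
            if m:
                name = m.group(1)
                if name not in network.index:
                    raise ParseError(f"line {lineno}: is_internal for undeclared node {name!r}")
                internal = m.group(2).upper() == "TRUE"
                network.node(name).is_internal = internal
                if not internal and name not in network.output_nodes:
                    network.output_nodes.append(name)
                if internal and name in network.output_nodes:
                    network.output_nodes.remove(name)
                continue
            raise ParseError(f"line {lineno}: cannot parse CFG statement {stmt!r}")
    return init


def _parse_istate(rhs: str, lineno: int) -> float:
    """Either a bare probability of ON, or the weighted form ``p [1], q [0]``."""
    if "[" not in rhs:
        p = float(rhs)
    else:
        p_on = 0.0
        total = 0.0
        for part in rhs.split(","):
            m = re.match(r"^\s*([\d.eE+-]+)\s*\[\s*([01])\s*\]\s*$", part)
            if not m:
                raise ParseError(f"line {lineno}: malformed istate term {part!r}")
            w, v = float(m.group(1)), int(m.group(2))
            total += w
            if v == 1:
                p_on += w
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ParseError(f"line {lineno}: istate weights must sum to 1 (got {total})")
        p = p_on
    if not 0.0 <= p <= 1.0:
        raise ParseError(f"line {lineno}: istate probability {p} outside [0,1]")
    return p


def parse_network(bnd_text: str, cfg_text: str = "") -> tuple[BooleanNetwork, InitialCondition]:
    """Parse BND + CFG texts; CFG parameter assignments override BND defaults."""
    network = parse_bnd(bnd_text)
    init = parse_cfg(cfg_text, network) if cfg_text.strip() else InitialCondition()
    for name, value in network.parameters.items():
        if math.isnan(value):
            raise ParseError(f"parameter ${name} referenced but never assigned")
    return network, init


def serialize_network(network: BooleanNetwork, init: InitialCondition | None = None
                      ) -> tuple[str, str]:
    """Write (bnd_text, cfg_text) in the same dialect ``parse_network`` reads."""
    blocks = []
    for spec in network.nodes:
        blocks.append(
            "node %s {\n  logic = %s;\n  rate_up = %s;\n  rate_down = %s;\n}" %
            (spec.name, spec.logic.source, spec.rate_up.source, spec.rate_down.source))
    bnd = "\n".join(blocks) + "\n"
    lines = [f"${k} = {v:g};" for k, v in sorted(network.parameters.items())]
    if init is not None:
        for name in sorted(init.probabilities):
            lines.append(f"{name}.istate = {init.probabilities[name]:g};")
    for spec in network.nodes:
        if not spec.is_internal:
            lines.append(f"{spec.name}.is_internal = FALSE;")
    return bnd, "\n".join(lines) + ("\n" if lines else "")


# ---------------------------------------------------------------------------
# Simulation
# ---------------------------------------------------------------------------

def evaluate_logic(network: BooleanNetwork, state: NetworkState, node: str) -> bool:
    """Truth value of ``node``'s logic expression in ``state``."""
    logic_fn, _, _ = network.compiled()[network.index[node]]
    return bool(logic_fn(state.bits, network.parameters))


def _pinned_indices(network: BooleanNetwork, mutants: Iterable[MutantSpec]) -> dict[int, bool]:
    pins: dict[int, bool] = {}
    for m in mutants:
        if m.node not in network.index:
            raise KeyError(f"mutant references unknown node {m.node!r}")
        pins[network.index[m.node]] = bool(m.forced_value)
    return pins


def apply_mutants(state: NetworkState, network: BooleanNetwork,
                  mutants: Iterable[MutantSpec]) -> None:
    """Pin forced nodes' bits in place."""
    for idx, val in _pinned_indices(network, mutants).items():
        state.bits[idx] = 1.0 if val else 0.0


def propensities(network: BooleanNetwork, state: NetworkState,
                 mutants: Sequence[MutantSpec] = ()) -> np.ndarray:
    """Per-node flip rate in the current state.

    A node currently OFF flips at its ``rate_up``, a node ON at its
    ``rate_down``; mutant-forced nodes have rate 0.
    """
    pins = _pinned_indices(network, mutants)
    bits = state.bits
    params = network.parameters
    rates = np.zeros(network.n_nodes)
    for i, (logic_fn, up_fn, down_fn) in enumerate(network.compiled()):
        if i in pins:
            continue
        logic = 1.0 if logic_fn(bits, params) else 0.0
        rate = down_fn(bits, params, logic) if bits[i] else up_fn(bits, params, logic)
        if rate < 0:
            raise ValueError(
                f"negative propensity {rate} for node {network.nodes[i].name} "
                f"in state {bits.astype(int).tolist()}")
        rates[i] = rate
    return rates


def gillespie_step(network: BooleanNetwork, state: NetworkState,
                   mutants: Sequence[MutantSpec], rng: np.random.Generator
                   ) -> tuple[NetworkState, float]:
    """One CTMC event: exponential dwell, then flip one node chosen with
    probability proportional to its rate.  At a fixed point returns the
    unchanged state with infinite dwell."""
    rates = propensities(network, state, mutants)
    total = float(rates.sum())
    if total == 0.0:
        return state, math.inf
    dwell = -math.log(rng.random()) / total
    threshold = rng.random() * total
    acc = 0.0
    chosen = len(rates) - 1
    for i, r in enumerate(rates):
        acc += r
        if threshold < acc:
            chosen = i
            break
    new_state = state.copy()
    new_state.bits[chosen] = 0.0 if new_state.bits[chosen] else 1.0
    new_state.boolean_time += dwell
    return new_state, dwell


def run_interval(network: BooleanNetwork, state: NetworkState,
                 mutants: Sequence[MutantSpec], delta: float,
                 rng: np.random.Generator) -> NetworkState:
    """Advance the CTMC by ``delta`` Boolean-time units (the last sampled
    event is discarded if its dwell overshoots the horizon)."""
    if delta < 0:
        raise ValueError("delta must be >= 0")
    horizon = state.boolean_time + delta
    current = state.copy()
    apply_mutants(current, network, mutants)
    # inline Gillespie loop with the pin set resolved once
    pins = _pinned_indices(network, mutants)
    bits = current.bits.tolist()  # plain list: faster scalar access in the loop
    params = network.parameters
    compiled = network.compiled()
    t = current.boolean_time
    n = network.n_nodes
    while True:
        total = 0.0
        rates = [0.0] * n
        for i in range(n):
            if i in pins:
                continue
            logic_fn, up_fn, down_fn = compiled[i]
            logic = 1.0 if logic_fn(bits, params) else 0.0
            rate = down_fn(bits, params, logic) if bits[i] else up_fn(bits, params, logic)
            if rate < 0:
                raise ValueError(f"negative propensity for node {network.nodes[i].name}")
            rates[i] = rate
            total += rate
        if total == 0.0:
            break
        t += -math.log(rng.random()) / total
        if t > horizon:
            break
        threshold = rng.random() * total
        acc = 0.0
        chosen = n - 1
        for i in range(n):
            acc += rates[i]
            if threshold < acc:
                chosen = i
                break
        bits[chosen] = 0.0 if bits[chosen] else 1.0
    current.bits = np.array(bits)
    current.boolean_time = horizon
    return current


def ensemble_run(network: BooleanNetwork, init: InitialCondition,
                 mutant_mixture: Sequence[tuple[Sequence[MutantSpec], float]] | None,
                 n_traj: int, t_max: float, window: float,
                 seed: int | np.random.Generator = 0):
    """Estimate node-activation probability time courses over an ensemble.

    Trajectories are allocated to mutant sets by largest-remainder rounding of
    the mixture weights; the reported course is the average over all
    trajectories (i.e. the weighted mixture).  Returns a pandas DataFrame
    indexed by time with one probability column per node.
    """
    import pandas as pd

    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    if mutant_mixture is None:
        mutant_mixture = [((), 1.0)]
    weights = np.array([w for _, w in mutant_mixture], dtype=float)
    if (weights < 0).any() or not math.isclose(weights.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("mixture weights must be >= 0 and sum to 1")
    counts = _largest_remainder(weights, n_traj)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    times = np.arange(0.0, t_max + 0.5 * window, window)
    acc = np.zeros((len(times), network.n_nodes))
    for (mutants, _), n_alloc in zip(mutant_mixture, counts):
        for _ in range(n_alloc):
            state = NetworkState(init.sample(network, rng))
            apply_mutants(state, network, mutants)
            prev_t = 0.0
            for j, t in enumerate(times):
                if t > prev_t:
                    state = run_interval(network, state, mutants, t - prev_t, rng)
                    prev_t = t
                acc[j] += state.bits
    probs = acc / n_traj
    names = [n.name for n in network.nodes]
    return pd.DataFrame(probs, index=pd.Index(times, name="boolean_time"), columns=names)


def _largest_remainder(weights: np.ndarray, total: int) -> list[int]:
    raw = weights * total
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    for i in range(short):
        counts[order[i]] += 1
    return counts.tolist()
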