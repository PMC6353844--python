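"""Logical-model input/output.

Parses, validates and serializes Boolean network models in a MaBoSS-dialect
text format: a BND file declaring one block per node with its logical rule,
and a CFG file carrying per-node simulation settings (initial-state
probabilities, activation/inactivation transition rates) plus global
simulation parameters.

The rule language supports the operators NOT (``!``), AND (``&``) and OR
(``|``), keyword spellings of the same operators, parentheses and the
literal constants ``0``/``1``.  Operator precedence is NOT > AND > OR.
Input nodes are encoded with the self-referential rule ``node = node``,
which is never enabled and therefore leaves the node at its initial value.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

__all__ = [
    "RuleAST",
    "Var",
    "Const",
    "Not",
    "And",
    "Or",
    "LogicalModel",
    "NodeSettings",
    "SimulationSettings",
    "ModelSyntaxError",
    "ModelValidationError",
    "parse_rule",
    "parse_bnd",
    "parse_cfg",
    "write_bnd",
    "write_cfg",
    "evaluate_rule",
    "model_to_json",
    "model_from_json",
]


class ModelSyntaxError(ValueError):
    """Raised on malformed BND/CFG text; carries 1-based line/column."""

    def __init__(self, message: str, line: int, column: int):
        super().__init__(f"line {line}, column {column}: {message}")
        self.line = line
        self.column = column


class ModelValidationError(ValueError):
    """Raised when a syntactically valid model violates a structural invariant."""


# ---------------------------------------------------------------------------
# Rule abstract syntax trees
# ---------------------------------------------------------------------------


class RuleAST:
    """Base class of Boolean rule expression nodes."""

    def evaluate(self, state: Mapping[str, bool]) -> bool:
        raise NotImplementedError

    def variables(self) -> set[str]:
        raise NotImplementedError

    def to_string(self) -> str:
        raise NotImplementedError

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"{type(self).__name__}({self.to_string()})"

    def __eq__(self, other) -> bool:
        return type(self) is type(other) and self._key() == other._key()

    def __hash__(self) -> int:
        return hash((type(self).__name__, self._key()))

    def _key(self):
        raise NotImplementedError


@dataclass(frozen=True, eq=False)
class Var(RuleAST):
    name: str

    def evaluate(self, state):
        try:
            return bool(state[self.name])
        except KeyError:
            raise KeyError(f"state does not assign node {self.name!r}") from None

    def variables(self):
        return {self.name}

    def to_string(self):
        return self.name

    def _key(self):
        return self.name


@dataclass(frozen=True, eq=False)
class Const(RuleAST):
    value: bool

    def evaluate(self, state):
        return self.value

    def variables(self):
        return set()

    def to_string(self):
        return "1" if self.value else "0"

    def _key(self):
        return self.value


@dataclass(frozen=True, eq=False)
class Not(RuleAST):
    operand: RuleAST

    def evaluate(self, state):
        return not self.operand.evaluate(state)

    def variables(self):
        return self.operand.variables()

    def to_string(self):
        inner = self.operand.to_string()
        if isinstance(self.operand, (And, Or)):
            inner = f"({inner})"
        return f"!{inner}"

    def _key(self):
        return self.operand


@dataclass(frozen=True, eq=False)
class And(RuleAST):
    left: RuleAST
    right: RuleAST

    def evaluate(self, state):
        return self.left.evaluate(state) and self.right.evaluate(state)

    def variables(self):
        return self.left.variables() | self.right.variables()

    def to_string(self):
        parts = []
        for op in (self.left, self.right):
            s = op.to_string()
            if isinstance(op, Or):
                s = f"({s})"
            parts.append(s)
        return " & ".join(parts)

    def _key(self):
        return (self.left, self.right)


@dataclass(frozen=True, eq=False)
class Or(RuleAST):
    left: RuleAST
    right: RuleAST

    def evaluate(self, state):
        return self.left.evaluate(state) or self.right.evaluate(state)

    def variables(self):
        return self.left.variables() | self.right.variables()

    def to_string(self):
        return f"{self.left.to_string()} | {self.right.to_string()}"

    def _key(self):
        return (self.left, self.right)


def evaluate_rule(rule: RuleAST, state: Mapping[str, bool]) -> bool:
    """Evaluate ``rule`` on a complete Boolean assignment.

    Raises ``KeyError`` if the state does not assign every node the rule
    references.
    """
    return rule.evaluate(state)


# ---------------------------------------------------------------------------
# Tokenizer / expression parser
# ---------------------------------------------------------------------------

_NAME_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")
_NUMBER_RE = re.compile(r"\d+\.?\d*(?:[eE][+-]?\d+)?|\.\d+(?:[eE][+-]?\d+)?")

_KEYWORD_OPS = {"NOT": "!", "AND": "&", "OR": "|"}


@dataclass
class _Token:
    kind: str  # 'name' | 'number' | operator/punct literal
    text: str
    line: int
    column: int


def _tokenize(text: str) -> Iterator[_Token]:
    line, col = 1, 1
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c == "\n":
            line += 1
            col = 1
            i += 1
            continue
        if c in " \t\r":
            i += 1
            col += 1
            continue
        if text.startswith("//", i):
            j = text.find("\n", i)
            if j == -1:
                break
            col += j - i
            i = j
            continue
        if text.startswith("/*", i):
            j = text.find("*/", i)
            if j == -1:
                raise ModelSyntaxError("unterminated comment", line, col)
            skipped = text[i : j + 2]
            nl = skipped.count("\n")
            if nl:
                line += nl
                col = len(skipped) - skipped.rfind("\n")
            else:
                col += len(skipped)
            i = j + 2
            continue
        m = _NAME_RE.match(text, i)
        if m:
            word = m.group(0)
            kind = "name"
            tok_text = word
            if word.upper() in _KEYWORD_OPS:
                kind = _KEYWORD_OPS[word.upper()]
                tok_text = kind
            yield _Token(kind, tok_text, line, col)
            col += len(word)
            i = m.end()
            continue
        m = _NUMBER_RE.match(text, i)
        if m:
            yield _Token("number", m.group(0), line, col)
            col += len(m.group(0))
            i = m.end()
            continue
        if text.startswith("&&", i) or text.startswith("||", i):
            yield _Token(text[i], text[i : i + 2], line, col)
            i += 2
            col += 2
            continue
        if c in "!&|(){}=;,?:@$[].":
            yield _Token(c, c, line, col)
            i += 1
            col += 1
            continue
        raise ModelSyntaxError(f"unexpected character {c!r}", line, col)


class _TokenStream:
    def __init__(self, text: str):
        self._tokens = list(_tokenize(text))
        self._pos = 0
        # position of end-of-text, for error messages
        nlines = text.count("\n") + 1
        self._eof = (nlines, len(text) - text.rfind("\n"))

    def peek(self) -> _Token | None:
        return self._tokens[self._pos] if self._pos < len(self._tokens) else None

    def next(self) -> _Token:
        tok = self.peek()
        if tok is None:
            raise ModelSyntaxError("unexpected end of input", *self._eof)
        self._pos += 1
        return tok

    def expect(self, kind: str) -> _Token:
        tok = self.next()
        if tok.kind != kind:
            raise ModelSyntaxError(
                f"expected {kind!r}, found {tok.text!r}", tok.line, tok.column
            )
        return tok

    def at(self, kind: str) -> bool:
        tok = self.peek()
        return tok is not None and tok.kind == kind


def _parse_or(ts: _TokenStream) -> RuleAST:
    node = _parse_and(ts)
    while ts.at("|"):
        ts.next()
        node = Or(node, _parse_and(ts))
    return node


def _parse_and(ts: _TokenStream) -> RuleAST:
    node = _parse_unary(ts)
    while ts.at("&"):
        ts.next()
        node = And(node, _parse_unary(ts))
    return node


def _parse_unary(ts: _TokenStream) -> RuleAST:
    if ts.at("!"):
        ts.next()
        return Not(_parse_unary(ts))
    return _parse_atom(ts)


def _parse_atom(ts: _TokenStream) -> RuleAST:
    tok = ts.next()
    if tok.kind == "(":
        node = _parse_or(ts)
        ts.expect(")")
        return node
    if tok.kind == "name":
        return Var(tok.text)
    if tok.kind == "number":
        if tok.text == "0":
            return Const(False)
        if tok.text == "1":
            return Const(True)
        raise ModelSyntaxError(
            f"only constants 0 and 1 are allowed in rules, found {tok.text!r}",
            tok.line,
            tok.column,
        )
    raise ModelSyntaxError(
        f"unexpected token {tok.text!r} in expression", tok.line, tok.column
    )


def parse_rule(text: str) -> RuleAST:
    """Parse a standalone Boolean rule expression."""
    ts = _TokenStream(text)
    node = _parse_or(ts)
    tok = ts.peek()
    if tok is not None:
        raise ModelSyntaxError(
            f"trailing input {tok.text!r} after expression", tok.line, tok.column
        )
    return node


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class LogicalModel:
    """A Boolean network: ordered node list, one rule per node.

    ``declared_outputs`` flags the phenotype read-out nodes (e.g.,
    Proliferation, Apoptosis).  ``rate_hints`` carries optional per-node
    (k_up, k_down) literals found in the BND source; they act as defaults
    below CFG-level settings and are not part of the model structure proper.
    """

    nodes: list[str]
    rules: dict[str, RuleAST]
    declared_outputs: list[str] = field(default_factory=list)
    rate_hints: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if len(set(self.nodes)) != len(self.nodes):
            dupes = sorted({n for n in self.nodes if self.nodes.count(n) > 1})
            raise ModelValidationError(f"duplicate node name(s): {dupes}")
        declared = set(self.nodes)
        if set(self.rules) != declared:
            missing = declared - set(self.rules)
            extra = set(self.rules) - declared
            raise ModelValidationError(
                f"rules not total: missing={sorted(missing)} extra={sorted(extra)}"
            )
        for node, rule in self.rules.items():
            undeclared = rule.variables() - declared
            if undeclared:
                raise ModelValidationError(
                    f"rule of {node!r} references undeclared node(s): "
                    f"{sorted(undeclared)}"
                )
        for out in self.declared_outputs:
            if out not in declared:
                raise ModelValidationError(f"declared output {out!r} is not a node")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def is_input(self, node: str) -> bool:
        """An input node carries the self-referential rule ``node = node``."""
        return self.rules[node] == Var(node)


@dataclass
class NodeSettings:
    """Per-node simulation settings.

    initial_prob is the probability that the node starts active; k_up/k_down
    are the 0→1 / 1→0 transition rates used when the node's rule enables the
    corresponding flip.  A node with one rate zeroed and a matching Boolean
    initial_prob is strictly fixed for the whole simulation.
    """

    initial_prob: float = 0.5
    k_up: float = 1.0
    k_down: float = 1.0
    is_internal: bool = False

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not 0.0 <= self.initial_prob <= 1.0:
            raise ModelValidationError(
                f"initial_prob must be in [0,1], got {self.initial_prob}"
            )
        if self.k_up < 0 or self.k_down < 0:
            raise ModelValidationError("transition rates must be nonnegative")
        if self.k_up == 0 and self.k_down == 0 and self.initial_prob not in (0.0, 1.0):
            raise ModelValidationError(
                "a node with both rates zero must be strictly fixed "
                "(initial_prob 0 or 1)"
            )


@dataclass
class SimulationSettings:
    """Simulation configuration: per-node settings plus global parameters."""

    node_settings: dict[str, NodeSettings]
    max_time: float = 50.0
    n_trajectories: int = 1000
    time_bins: int = 100
    seed: int = 0
    asymptotic_window: float = 0.1

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.max_time <= 0:
            raise ModelValidationError("max_time must be positive")
        if self.n_trajectories < 1:
            raise ModelValidationError("n_trajectories must be >= 1")
        if self.time_bins < 1:
            raise ModelValidationError("time_bins must be >= 1")
        if not 0.0 < self.asymptotic_window <= 1.0:
            raise ModelValidationError("asymptotic_window must be in (0, 1]")
        for node, ns in self.node_settings.items():
            try:
                ns.validate()
            except ModelValidationError as exc:
                raise ModelValidationError(f"node {node!r}: {exc}") from None

    def copy(self) -> "SimulationSettings":
        return SimulationSettings(
            node_settings={k: replace(v) for k, v in self.node_settings.items()},
            max_time=self.max_time,
            n_trajectories=self.n_trajectories,
            time_bins=self.time_bins,
            seed=self.seed,
            asymptotic_window=self.asymptotic_window,
        )

    @classmethod
    def defaults_for(cls, model: LogicalModel, **kwargs) -> "SimulationSettings":
        """Default settings: initial_prob 0.5, all rates 1, honoring any BND
        rate hints."""
        ns = {}
        for node in model.nodes:
            ku, kd = model.rate_hints.get(node, (1.0, 1.0))
            ns[node] = NodeSettings(initial_prob=0.5, k_up=ku, k_down=kd)
        return cls(node_settings=ns, **kwargs)


# ---------------------------------------------------------------------------
# BND parsing / serialization
# ---------------------------------------------------------------------------


def _parse_rate_value(ts: _TokenStream, direction: str) -> float:
    """Parse a rate right-hand side: a numeric literal, or the reference
    tool's conditional form ``@logic ? a : b`` which is normalized to the
    scalar rate of the relevant branch (the rule-true branch for rate_up,
    the rule-false branch for rate_down)."""
    if ts.at("@"):
        ts.next()
        kw = ts.expect("name")
        if kw.text != "logic":
            raise ModelSyntaxError(
                f"expected 'logic' after '@', found {kw.text!r}", kw.line, kw.column
            )
        ts.expect("?")
        true_tok = ts.expect("number")
        ts.expect(":")
        false_tok = ts.expect("number")
        chosen = true_tok if direction == "up" else false_tok
        other = false_tok if direction == "up" else true_tok
        if float(other.text) != 0.0:
            raise ModelSyntaxError(
                "conditional rates must be 0 on the rule-disabled branch",
                other.line,
                other.column,
            )
        return float(chosen.text)
    tok = ts.expect("number")
    return float(tok.text)


def parse_bnd(text: str) -> LogicalModel:
    """Parse BND-dialect source into a :class:`LogicalModel`.

    Each node block has the form::

        node NAME {
          logic = <expr>;
          rate_up = <number or @logic ? u : 0>;    // optional
          rate_down = <number or @logic ? 0 : d>;  // optional
        }
    """
    ts = _TokenStream(text)
    nodes: list[str] = []
    rules: dict[str, RuleAST] = {}
    rate_hints: dict[str, tuple[float, float]] = {}
    while ts.peek() is not None:
        kw = ts.expect("name")
        if kw.text.lower() != "node":
            raise ModelSyntaxError(
                f"expected 'node', found {kw.text!r}", kw.line, kw.column
            )
        name_tok = ts.expect("name")
        name = name_tok.text
        if name in rules:
            raise ModelSyntaxError(
                f"duplicate node {name!r}", name_tok.line, name_tok.column
            )
        ts.expect("{")
        rule: RuleAST | None = None
        k_up: float | None = None
        k_down: float | None = None
        while not ts.at("}"):
            attr = ts.expect("name")
            ts.expect("=")
            if attr.text.lower() == "logic":
                rule = _parse_or(ts)
            elif attr.text.lower() == "rate_up":
                k_up = _parse_rate_value(ts, "up")
            elif attr.text.lower() == "rate_down":
                k_down = _parse_rate_value(ts, "down")
            else:
                raise ModelSyntaxError(
                    f"unknown node attribute {attr.text!r}", attr.line, attr.column
                )
            ts.expect(";")
        ts.expect("}")
        if rule is None:
            raise ModelSyntaxError(
                f"node {name!r} has no logic rule", name_tok.line, name_tok.column
            )
        nodes.append(name)
        rules[name] = rule
        if k_up is not None or k_down is not None:
            rate_hints[name] = (
                1.0 if k_up is None else k_up,
                1.0 if k_down is None else k_down,
            )
    return LogicalModel(nodes=nodes, rules=rules, rate_hints=rate_hints)


def write_bnd(model: LogicalModel) -> str:
    """Serialize a model to BND-dialect text (round-trips through
    :func:`parse_bnd` up to whitespace)."""
    blocks = []
    for node in model.nodes:
        lines = [f"node {node} {{", f"  logic = {model.rules[node].to_string()};"]
        if node in model.rate_hints:
            ku, kd = model.rate_hints[node]
            lines.append(f"  rate_up = {ku!r};")
            lines.append(f"  rate_down = {kd!r};")
        lines.append("}")
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + "\n"


# ---------------------------------------------------------------------------
# CFG parsing / serialization
# ---------------------------------------------------------------------------

_GLOBAL_KEYS = {
    "max_time": float,
    "time_bins": int,
    "trajectories": int,
    "seed": int,
    "asymptotic_window": float,
}

_NODE_ATTRS = {"istate", "rate_up", "rate_down", "is_internal"}


def parse_cfg(text: str, model: LogicalModel) -> SimulationSettings:
    """Parse CFG-dialect source against an already-parsed model.

    Statements (``;``-terminated, ``//`` comments allowed)::

        NAME.istate = 0.6;
        NAME.rate_up = 100;
        NAME.rate_down = 0.01;
        NAME.is_internal = TRUE;
        max_time = 50; time_bins = 100; trajectories = 1000;
        seed = 42; asymptotic_window = 0.1;

    Nodes absent from the text receive defaults (initial_prob 0.5, rates 1,
    or the BND rate hints where present).
    """
    settings = SimulationSettings.defaults_for(model)
    ts = _TokenStream(text)
    declared = set(model.nodes)
    while ts.peek() is not None:
        name_tok = ts.expect("name")
        if ts.at("."):
            ts.next()
            attr_tok = ts.expect("name")
            attr = attr_tok.text.lower()
            if attr not in _NODE_ATTRS:
                raise ModelSyntaxError(
                    f"unknown node attribute {attr_tok.text!r}",
                    attr_tok.line,
                    attr_tok.column,
                )
            if name_tok.text not in declared:
                raise ModelSyntaxError(
                    f"unknown node {name_tok.text!r}", name_tok.line, name_tok.column
                )
            ts.expect("=")
            ns = settings.node_settings[name_tok.text]
            if attr == "is_internal":
                val_tok = ts.next()
                truthy = {"true": True, "false": False, "1": True, "0": False}
                key = val_tok.text.lower()
                if key not in truthy:
                    raise ModelSyntaxError(
                        f"expected boolean, found {val_tok.text!r}",
                        val_tok.line,
                        val_tok.column,
                    )
                ns.is_internal = truthy[key]
            else:
                val_tok = ts.expect("number")
                value = float(val_tok.text)
                if attr == "istate":
                    if not 0.0 <= value <= 1.0:
                        raise ModelSyntaxError(
                            f"istate must be in [0,1], got {value}",
                            val_tok.line,
                            val_tok.column,
                        )
                    ns.initial_prob = value
                elif attr == "rate_up":
                    ns.k_up = value
                else:
                    ns.k_down = value
            ts.expect(";")
        else:
            key = name_tok.text.lower()
            if key not in _GLOBAL_KEYS:
                raise ModelSyntaxError(
                    f"unknown setting {name_tok.text!r}", name_tok.line, name_tok.column
                )
            ts.expect("=")
            val_tok = ts.expect("number")
            setattr(settings, key if key != "trajectories" else "n_trajectories",
                    _GLOBAL_KEYS[key](float(val_tok.text)))
            ts.expect(";")
    settings.validate()
    return settings


def write_cfg(settings: SimulationSettings, model: LogicalModel) -> str:
    """Serialize settings to CFG-dialect text; exact round-trip through
    :func:`parse_cfg` (floats written with ``repr``)."""
    settings.validate()
    lines = [
        f"max_time = {settings.max_time!r};",
        f"time_bins = {settings.time_bins};",
        f"trajectories = {settings.n_trajectories};",
        f"seed = {settings.seed};",
        f"asymptotic_window = {settings.asymptotic_window!r};",
        "",
    ]
    for node in model.nodes:
        ns = settings.node_settings[node]
        lines.append(f"{node}.istate = {ns.initial_prob!r};")
        lines.append(f"{node}.rate_up = {ns.k_up!r};")
        lines.append(f"{node}.rate_down = {ns.k_down!r};")
        if ns.is_internal:
            lines.append(f"{node}.is_internal = TRUE;")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# JSON interchange
# ---------------------------------------------------------------------------


def model_to_json(model: LogicalModel) -> str:
    payload = {
        "nodes": model.nodes,
        "rules": {n: model.rules[n].to_string() for n in model.nodes},
        "declared_outputs": model.declared_outputs,
        "rate_hints": {n: list(v) for n, v in model.rate_hints.items()},
    }
    return json.dumps(payload, indent=2)


def model_from_json(text: str) -> LogicalModel:
    payload = json.loads(text)
    return LogicalModel(
        nodes=list(payload["nodes"]),
        rules={n: parse_rule(r) for n, r in payload["rules"].items()},
        declared_outputs=list(payload.get("declared_outputs", [])),
        rate_hints={n: tuple(v) for n, v in payload.get("rate_hints", {}).items()},
    )
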