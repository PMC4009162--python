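"""Synchronous Boolean gene-regulatory networks.

A network is a set of named genes, each carrying a Boolean update rule
written over the other genes with ``& | !``, parentheses and the constants
``0``/``1``.  Rules are stored as expression trees; the regulatory edge set
is derived from the variables each rule reads.  Link knockouts ("clamps")
force a single regulatory input, as read by one specific target gene, to
constant false while leaving the source gene itself untouched.

State encoding convention: the first declared gene is the least significant
bit of the integer state index, so ``index = sum(bits[k] << k)``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Expr",
    "Var",
    "Const",
    "Not",
    "And",
    "Or",
    "BooleanNetwork",
    "NetworkState",
    "NetworkError",
    "NetworkSyntaxError",
    "NetworkValidationError",
    "parse_expression",
    "parse_network",
    "serialize_network",
    "network_to_json",
    "network_from_json",
    "evaluate_gene",
    "knockout_link",
    "encode_state",
    "decode_state",
]


class NetworkError(ValueError):
    """Base class for network definition problems."""


class NetworkSyntaxError(NetworkError):
    """Malformed rule text; carries a 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line else message)


class NetworkValidationError(NetworkError):
    """Structurally invalid network (undefined genes, duplicates, ...)."""


# ---------------------------------------------------------------------------
# Expression trees
# ---------------------------------------------------------------------------


class Expr:
    """Base class for Boolean expression nodes."""

    def evaluate(self, env) -> bool:
        raise NotImplementedError

    def variables(self) -> list[str]:
        """Input gene names in order of first appearance."""
        out: list[str] = []
        self._collect(out)
        return out

    def _collect(self, out: list[str]) -> None:
        raise NotImplementedError

    def unparse(self) -> str:
        raise NotImplementedError

    # precedence used for minimal parenthesisation: Or=1, And=2, Not=3, atom=4
    _prec = 4

    def _sub(self, child: "Expr") -> str:
        s = child.unparse()
        return f"({s})" if child._prec < self._prec else s

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.unparse()


@dataclass(frozen=True)
class Var(Expr):
    name: str
    _prec = 4

    def evaluate(self, env) -> bool:
        return bool(env(self.name))

    def _collect(self, out):
        if self.name not in out:
            out.append(self.name)

    def unparse(self) -> str:
        return self.name


@dataclass(frozen=True)
class Const(Expr):
    value: bool
    _prec = 4

    def evaluate(self, env) -> bool:
        return self.value

    def _collect(self, out):
        pass

    def unparse(self) -> str:
        return "1" if self.value else "0"


@dataclass(frozen=True)
class Not(Expr):
    operand: Expr
    _prec = 3

    def evaluate(self, env) -> bool:
        return not self.operand.evaluate(env)

    def _collect(self, out):
        self.operand._collect(out)

    def unparse(self) -> str:
        return "!" + self._sub(self.operand)


@dataclass(frozen=True)
class And(Expr):
    left: Expr
    right: Expr
    _prec = 2

    def evaluate(self, env) -> bool:
        return self.left.evaluate(env) and self.right.evaluate(env)

    def _collect(self, out):
        self.left._collect(out)
        self.right._collect(out)

    def unparse(self) -> str:
        return f"{self._sub(self.left)} & {self._sub(self.right)}"


@dataclass(frozen=True)
class Or(Expr):
    left: Expr
    right: Expr
    _prec = 1

    def evaluate(self, env) -> bool:
        return self.left.evaluate(env) or self.right.evaluate(env)

    def _collect(self, out):
        self.left._collect(out)
        self.right._collect(out)

    def unparse(self) -> str:
        return f"{self._sub(self.left)} | {self._sub(self.right)}"


_TOKEN_RE = re.compile(
    r"\s*(?:(?P<ident>[A-Za-z_][A-Za-z0-9_.\-]*)|(?P<const>[01])|(?P<op>[&|!()]))"
)


def _tokenize(text: str, line: int | None = None) -> list[tuple[str, str]]:
    tokens: list[tuple[str, str]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            if text[pos:].strip() == "":
                break
            raise NetworkSyntaxError(
                f"unexpected character {text[pos:].strip()[0]!r} in expression", line
            )
        pos = m.end()
        if m.group("ident") is not None:
            tokens.append(("ident", m.group("ident")))
        elif m.group("const") is not None:
            tokens.append(("const", m.group("const")))
        else:
            tokens.append(("op", m.group("op")))
    return tokens


class _Parser:
    """Recursive-descent parser: expr := term ('|' term)*, term := factor
    ('&' factor)*, factor := '!' factor | '(' expr ')' | ident | const."""

    def __init__(self, tokens: list[tuple[str, str]], line: int | None):
        self.tokens = tokens
        self.i = 0
        self.line = line

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else (None, None)

    def pop(self):
        tok = self.peek()
        self.i += 1
        return tok

    def parse(self) -> Expr:
        e = self.expr()
        kind, val = self.peek()
        if kind is not None:
            raise NetworkSyntaxError(f"unexpected token {val!r}", self.line)
        return e

    def expr(self) -> Expr:
        e = self.term()
        while self.peek() == ("op", "|"):
            self.pop()
            e = Or(e, self.term())
        return e

    def term(self) -> Expr:
        e = self.factor()
        while self.peek() == ("op", "&"):
            self.pop()
            e = And(e, self.factor())
        return e

    def factor(self) -> Expr:
        kind, val = self.pop()
        if kind == "op" and val == "!":
            return Not(self.factor())
        if kind == "op" and val == "(":
            e = self.expr()
            kind, val = self.pop()
            if (kind, val) != ("op", ")"):
                raise NetworkSyntaxError("missing closing parenthesis", self.line)
            return e
        if kind == "ident":
            return Var(val)
        if kind == "const":
            return Const(val == "1")
        raise NetworkSyntaxError("empty or truncated expression", self.line)


def parse_expression(text: str, line: int | None = None) -> Expr:
    """Parse a single Boolean rule expression."""
    return _Parser(_tokenize(text, line), line).parse()


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BooleanNetwork:
    """An n-gene synchronous Boolean network.

    Parameters
    ----------
    genes
        Ordered unique gene names; position in this tuple fixes the bit
        position in the integer state encoding (gene 0 = least significant).
    rules
        Per-gene update expression; every gene must have a rule and every
        variable read by a rule must itself be a gene.
    clamps
        Set of ``(source, target)`` link knockouts: when evaluating
        ``target``'s rule, the input ``source`` reads as constant false.
    """

    genes: tuple[str, ...]
    rules: Mapping[str, Expr]
    clamps: frozenset = frozenset()

    def __post_init__(self):
        object.__setattr__(self, "genes", tuple(self.genes))
        object.__setattr__(self, "rules", dict(self.rules))
        object.__setattr__(
            self, "clamps", frozenset((s, t) for s, t in self.clamps)
        )
        self._validate()

    def _validate(self) -> None:
        if len(self.genes) < 1:
            raise NetworkValidationError("network needs at least one gene")
        if any(not g for g in self.genes):
            raise NetworkValidationError("empty gene name")
        if len(set(self.genes)) != len(self.genes):
            raise NetworkValidationError("duplicate gene names")
        gene_set = set(self.genes)
        missing_rules = gene_set - set(self.rules)
        if missing_rules:
            raise NetworkValidationError(
                f"genes without update rules: {sorted(missing_rules)}"
            )
        extra = set(self.rules) - gene_set
        if extra:
            raise NetworkValidationError(f"rules for undeclared genes: {sorted(extra)}")
        for g in self.genes:
            for v in self.rules[g].variables():
                if v not in gene_set:
                    raise NetworkValidationError(
                        f"rule for {g!r} references undefined gene {v!r}"
                    )
        edge_set = {
            (src, tgt) for tgt in self.genes for src in self.rules[tgt].variables()
        }
        for s, t in self.clamps:
            if (s, t) not in edge_set:
                raise NetworkValidationError(f"clamp on nonexistent link {s}->{t}")

    # -- basic structure ----------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.genes)

    def gene_index(self, gene: str) -> int:
        try:
            return self.genes.index(gene)
        except ValueError:
            raise NetworkValidationError(f"unknown gene {gene!r}") from None

    def inputs(self, gene: str) -> tuple[str, ...]:
        """Declared regulators of ``gene`` (order of first appearance)."""
        self.gene_index(gene)
        return tuple(self.rules[gene].variables())

    @property
    def edges(self) -> frozenset:
        """All (source, target) regulatory links, clamped ones included."""
        return frozenset(
            (src, tgt) for tgt in self.genes for src in self.rules[tgt].variables()
        )

    # -- semantics ----------------------------------------------------------

    def truth_table(self, gene: str) -> np.ndarray:
        """Boolean output column over the 2^fan-in input rows.

        Row index encodes the input values with the first declared input as
        the least significant bit.  Clamps are applied, so a clamped input
        column has no effect on the output.
        """
        inp = self.inputs(gene)
        k = len(inp)
        out = np.zeros(2**k, dtype=bool)
        clamped = {s for s, t in self.clamps if t == gene}
        for row in range(2**k):
            env_vals = {
                name: (False if name in clamped else bool((row >> j) & 1))
                for j, name in enumerate(inp)
            }
            out[row] = self.rules[gene].evaluate(lambda v: env_vals[v])
        return out

    def with_clamp(self, source: str, target: str) -> "BooleanNetwork":
        if (source, target) not in self.edges:
            raise NetworkValidationError(
                f"no regulatory link {source}->{target} to knock out"
            )
        if (source, target) in self.clamps:
            raise NetworkValidationError(
                f"link {source}->{target} is already knocked out"
            )
        return BooleanNetwork(self.genes, self.rules, self.clamps | {(source, target)})


@dataclass(frozen=True)
class NetworkState:
    """A full gene-expression state: bit vector plus integer encoding."""

    bits: tuple[int, ...]
    index: int

    @classmethod
    def from_bits(cls, bits: Sequence[int]) -> "NetworkState":
        bits = tuple(int(bool(b)) for b in bits)
        return cls(bits, encode_state(bits))

    @classmethod
    def from_index(cls, index: int, n: int) -> "NetworkState":
        return cls(tuple(decode_state(index, n)), int(index))


def encode_state(bits: Sequence[int]) -> int:
    """Integer index of a bit vector; bit 0 (first gene) is least significant."""
    return int(sum((1 << k) for k, b in enumerate(bits) if b))


def decode_state(index: int, n: int) -> list[int]:
    """Bit vector of length ``n`` for a state index."""
    if not 0 <= index < 2**n:
        raise ValueError(f"state index {index} out of range for {n} genes")
    return [(index >> k) & 1 for k in range(n)]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def evaluate_gene(net: BooleanNetwork, gene: str, state) -> bool:
    """Next value of ``gene`` given the current network state.

    ``state`` may be an integer index, a bit sequence, or a
    :class:`NetworkState`.  Clamped inputs read as false.
    """
    idx = net.gene_index(gene)  # raises on unknown gene
    del idx
    if isinstance(state, NetworkState):
        bits = state.bits
    elif isinstance(state, (int, np.integer)):
        bits = decode_state(int(state), net.n)
    else:
        bits = [int(bool(b)) for b in state]
        if len(bits) != net.n:
            raise ValueError(f"state has {len(bits)} bits, expected {net.n}")
    clamped = {s for s, t in net.clamps if t == gene}

    def env(name: str) -> bool:
        if name in clamped:
            return False
        return bool(bits[net.gene_index(name)])

    return bool(net.rules[gene].evaluate(env))


def knockout_link(net: BooleanNetwork, source: str, target: str) -> BooleanNetwork:
    """Knock out one regulatory link: ``target`` reads ``source`` as false.

    Returns a new network; the original is unmodified.  The link stays in
    ``edges`` but is recorded in ``clamps``.  Other targets of ``source``
    are unaffected, as is ``source``'s own state.
    """
    net.gene_index(source)
    net.gene_index(target)
    return net.with_clamp(source, target)


# ---------------------------------------------------------------------------
# BoolNet-style text format
# ---------------------------------------------------------------------------

_HEADER_RE = re.compile(r"^\s*targets\s*,\s*factors\s*$", re.IGNORECASE)


def parse_network(text: str) -> BooleanNetwork:
    """Parse a BoolNet-style document: a ``targets, factors`` header line
    followed by one ``gene, expression`` line per gene.

    Blank lines and ``#`` comments are ignored.  Every gene referenced by
    any expression must have its own rule line.
    """
    genes: list[str] = []
    rules: dict[str, Expr] = {}
    header_seen = False
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if not header_seen:
            if not _HEADER_RE.match(line):
                raise NetworkSyntaxError(
                    "expected header 'targets, factors'", lineno
                )
            header_seen = True
            continue
        if "," not in line:
            raise NetworkSyntaxError("expected 'gene, expression'", lineno)
        name, expr_text = line.split(",", 1)
        name = name.strip()
        if not re.fullmatch(r"[A-Za-z_][A-Za-z0-9_.\-]*", name):
            raise NetworkSyntaxError(f"invalid gene name {name!r}", lineno)
        if name in rules:
            raise NetworkSyntaxError(f"duplicate rule for gene {name!r}", lineno)
        genes.append(name)
        rules[name] = parse_expression(expr_text, lineno)
    if not header_seen:
        raise NetworkSyntaxError("empty document: missing 'targets, factors' header")
    if not genes:
        raise NetworkValidationError("no gene rules after header")
    return BooleanNetwork(tuple(genes), rules)


def serialize_network(net: BooleanNetwork) -> str:
    """Render back to the BoolNet-style dialect (clamps are not expressible
    in the text dialect; serialize the JSON form to keep them)."""
    lines = ["targets, factors"]
    for g in net.genes:
        lines.append(f"{g}, {net.rules[g].unparse()}")
    return "\n".join(lines) + "\n"


def network_to_json(net: BooleanNetwork) -> str:
    """JSON dialect: genes, rule strings, and applied link knockouts."""
    return json.dumps(
        {
            "genes": list(net.genes),
            "rules": {g: net.rules[g].unparse() for g in net.genes},
            "clamps": sorted([list(c) for c in net.clamps]),
        },
        indent=2,
    )


def network_from_json(text: str) -> BooleanNetwork:
    doc = json.loads(text)
    genes = tuple(doc["genes"])
    rules = {g: parse_expression(r) for g, r in doc["rules"].items()}
    clamps = frozenset((s, t) for s, t in doc.get("clamps", []))
    return BooleanNetwork(genes, rules, clamps)
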