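"""Boolean expressions: AST, parsing, evaluation, substitution, constancy.

Expressions are built from constants 0/1, variable references, negation
(``!``), conjunction (``&``) and disjunction (``|``).  They are immutable and
hashable.  Substitution applies the standard identity/absorption rules for
constants so that a fully substituted expression collapses to a constant.
Whether an expression is *semantically* constant is decided by a truth-table
sweep over its referenced variables, never by syntactic shape alone.
"""

from __future__ import annotations

import itertools
import re
from typing import Iterator, Mapping, Optional


class BnetSyntaxError(ValueError):
    """Raised for malformed expression or network source text."""

    def __init__(self, message: str, line: Optional[int] = None, column: Optional[int] = None):
        self.line = line
        self.column = column
        where = ""
        if line is not None:
            where = f" (line {line}" + (f", column {column}" if column is not None else "") + ")"
        super().__init__(message + where)


class Expression:
    """Base class of the Boolean expression AST."""

    __slots__ = ()

    def variables(self) -> frozenset[str]:
        """The set of variable names referenced anywhere in the expression."""
        raise NotImplementedError

    def evaluate(self, assignment: Mapping[str, int]) -> int:
        """Evaluate to a bit under a (at least covering) variable assignment."""
        raise NotImplementedError

    def substitute(self, partial: Mapping[str, int]) -> "Expression":
        """Replace variables by constants and fold constants away."""
        raise NotImplementedError

    def to_python(self, bitref) -> str:
        """Render as a Python boolean expression; ``bitref(v)`` renders a variable."""
        raise NotImplementedError

    def __str__(self) -> str:
        return format_expression(self)

    def __repr__(self) -> str:
        return f"{type(self).__name__}({format_expression(self)!r})"

    # -- semantic queries ---------------------------------------------------

    def constancy(self, partial: Mapping[str, int] | None = None) -> Optional[int]:
        """Return 0 or 1 if the expression is semantically constant under
        ``partial``, else ``None``.

        Decided by enumerating all assignments of the free referenced
        variables, so non-simplified but constant expressions (e.g.
        ``v | !v``) are recognized.
        """
        partial = partial or {}
        free = sorted(self.variables() - partial.keys())
        if len(free) > 20:
            raise ValueError(
                f"constancy check over {len(free)} free variables is not tractable"
            )
        env = dict(partial)
        first: Optional[int] = None
        for bits in itertools.product((0, 1), repeat=len(free)):
            env.update(zip(free, bits))
            value = self.evaluate(env)
            if first is None:
                first = value
            elif value != first:
                return None
        return first


def depends_on(e: Expression, u: str) -> bool:
    """Whether ``e`` semantically depends on variable ``u``: some assignment
    of the other referenced variables changes the value when u toggles."""
    if u not in e.variables():
        return False
    others = sorted(e.variables() - {u})
    if len(others) > 20:
        raise ValueError("dependency check is not tractable")
    for bits in itertools.product((0, 1), repeat=len(others)):
        env = dict(zip(others, bits))
        env[u] = 0
        a = e.evaluate(env)
        env[u] = 1
        if e.evaluate(env) != a:
            return True
    return False


class Const(Expression):
    __slots__ = ("value",)

    def __init__(self, value: int):
        object.__setattr__(self, "value", int(value))

    def __setattr__(self, *a):  # immutability
        raise AttributeError("Const is immutable")

    def variables(self) -> frozenset[str]:
        return frozenset()

    def evaluate(self, assignment) -> int:
        return self.value

    def substitute(self, partial) -> Expression:
        return self

    def to_python(self, bitref) -> str:
        return "True" if self.value else "False"

    def __eq__(self, other):
        return isinstance(other, Const) and other.value == self.value

    def __hash__(self):
        return hash(("const", self.value))


class Var(Expression):
    __slots__ = ("name",)

    def __init__(self, name: str):
        object.__setattr__(self, "name", name)

    def __setattr__(self, *a):
        raise AttributeError("Var is immutable")

    def variables(self) -> frozenset[str]:
        return frozenset((self.name,))

    def evaluate(self, assignment) -> int:
        try:
            return int(assignment[self.name])
        except KeyError:
            raise KeyError(f"assignment is missing variable {self.name!r}") from None

    def substitute(self, partial) -> Expression:
        if self.name in partial:
            return Const(partial[self.name])
        return self

    def to_python(self, bitref) -> str:
        return bitref(self.name)

    def __eq__(self, other):
        return isinstance(other, Var) and other.name == self.name

    def __hash__(self):
        return hash(("var", self.name))


class Not(Expression):
    __slots__ = ("child",)

    def __init__(self, child: Expression):
        object.__setattr__(self, "child", child)

    def __setattr__(self, *a):
        raise AttributeError("Not is immutable")

    def variables(self) -> frozenset[str]:
        return self.child.variables()

    def evaluate(self, assignment) -> int:
        return 1 - self.child.evaluate(assignment)

    def substitute(self, partial) -> Expression:
        inner = self.child.substitute(partial)
        if isinstance(inner, Const):
            return Const(1 - inner.value)
        if isinstance(inner, Not):
            return inner.child
        return Not(inner)

    def to_python(self, bitref) -> str:
        return f"(not {self.child.to_python(bitref)})"

    def __eq__(self, other):
        return isinstance(other, Not) and other.child == self.child

    def __hash__(self):
        return hash(("not", self.child))


class _Nary(Expression):
    """Shared machinery of n-ary conjunction/disjunction."""

    __slots__ = ("args",)
    _neutral = None  # value dropped from args
    _dominant = None  # value that forces the whole expression

    def __init__(self, args):
        object.__setattr__(self, "args", tuple(args))

    def __setattr__(self, *a):
        raise AttributeError("expression nodes are immutable")

    def variables(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for a in self.args:
            out |= a.variables()
        return out

    def substitute(self, partial) -> Expression:
        new = []
        for a in self.args:
            s = a.substitute(partial)
            if isinstance(s, Const):
                if s.value == self._dominant:
                    return Const(self._dominant)
                continue  # neutral element, drop
            if isinstance(s, type(self)):
                new.extend(s.args)
            else:
                new.append(s)
        if not new:
            return Const(self._neutral)
        if len(new) == 1:
            return new[0]
        return type(self)(new)

    def __eq__(self, other):
        return type(other) is type(self) and other.args == self.args

    def __hash__(self):
        return hash((type(self).__name__, self.args))


class And(_Nary):
    __slots__ = ()
    _neutral = 1
    _dominant = 0

    def evaluate(self, assignment) -> int:
        for a in self.args:
            if not a.evaluate(assignment):
                return 0
        return 1

    def to_python(self, bitref) -> str:
        if not self.args:
            return "True"
        return "(" + " and ".join(a.to_python(bitref) for a in self.args) + ")"


class Or(_Nary):
    __slots__ = ()
    _neutral = 0
    _dominant = 1

    def evaluate(self, assignment) -> int:
        for a in self.args:
            if a.evaluate(assignment):
                return 1
        return 0

    def to_python(self, bitref) -> str:
        if not self.args:
            return "False"
        return "(" + " or ".join(a.to_python(bitref) for a in self.args) + ")"


# ---------------------------------------------------------------------------
# parsing


NAME_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*")

_TOKEN_RE = re.compile(
    r"\s*(?:(?P<name>[A-Za-z_][A-Za-z0-9_]*)|(?P<const>[01])|(?P<op>[!&|()])|(?P<bad>\S))"
)


def _tokenize(text: str, line: Optional[int]) -> Iterator[tuple[str, str, int]]:
    for m in _TOKEN_RE.finditer(text):
        col = m.start(m.lastgroup) + 1
        if m.lastgroup == "bad":
            raise BnetSyntaxError(f"unexpected character {m.group('bad')!r}", line, col)
        yield m.lastgroup, m.group(m.lastgroup), col


def parse_expression(text: str, line: Optional[int] = None) -> Expression:
    """Parse an expression in the ``.bnet`` dialect.

    Grammar (loosest binding first)::

        disjunction ::= conjunction ('|' conjunction)*
        conjunction ::= unary ('&' unary)*
        unary       ::= '!' unary | '(' disjunction ')' | name | '0' | '1'
    """
    tokens = list(_tokenize(text, line))
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else (None, None, len(text) + 1)

    def take():
        nonlocal pos
        tok = peek()
        pos += 1
        return tok

    def disjunction() -> Expression:
        terms = [conjunction()]
        while peek()[:2] == ("op", "|"):
            take()
            terms.append(conjunction())
        return terms[0] if len(terms) == 1 else Or(terms)

    def conjunction() -> Expression:
        factors = [unary()]
        while peek()[:2] == ("op", "&"):
            take()
            factors.append(unary())
        return factors[0] if len(factors) == 1 else And(factors)

    def unary() -> Expression:
        kind, value, col = take()
        if kind == "op" and value == "!":
            return Not(unary())
        if kind == "op" and value == "(":
            inner = disjunction()
            kind2, value2, col2 = take()
            if (kind2, value2) != ("op", ")"):
                raise BnetSyntaxError("expected ')'", line, col2)
            return inner
        if kind == "name":
            return Var(value)
        if kind == "const":
            return Const(int(value))
        raise BnetSyntaxError(
            "expected a variable, constant, '!' or '('"
            + (f", found {value!r}" if value else " at end of expression"),
            line,
            col,
        )

    if not tokens:
        raise BnetSyntaxError("empty expression", line)
    expr = disjunction()
    if pos != len(tokens):
        kind, value, col = peek()
        raise BnetSyntaxError(f"unexpected trailing token {value!r}", line, col)
    return expr


def format_expression(e: Expression) -> str:
    """Render an expression in the ``.bnet`` dialect (parse round-trips)."""
    if isinstance(e, Const):
        return str(e.value)
    if isinstance(e, Var):
        return e.name
    if isinstance(e, Not):
        inner = format_expression(e.child)
        if isinstance(e.child, (And, Or)):
            inner = f"({inner})"
        return f"!{inner}"
    if isinstance(e, And):
        parts = []
        for a in e.args:
            s = format_expression(a)
            if isinstance(a, Or):
                s = f"({s})"
            parts.append(s)
        return " & ".join(parts)
    if isinstance(e, Or):
        return " | ".join(format_expression(a) for a in e.args)
    raise TypeError(f"not an expression: {e!r}")
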