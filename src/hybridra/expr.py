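"""Boolean expression ASTs.

The update rule of every regulatory component is a finite expression tree
over ``{0, 1, variable, NOT, AND, OR}``.  Trees are immutable; all
manipulation (substitution, simplification) returns new trees.

A small concrete syntax is supported for fixtures and tests::

    A & !B | (C & 1)

with ``!`` binding tightest, then ``&``, then ``|``.  Identifiers may
contain letters, digits, ``_``, ``/`` and ``:`` (complex species names such
as ``IKBA/NFKB1/RELA`` are single identifiers).
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Iterable, Mapping

from .errors import ParseError

__all__ = [
    "LogicExpr", "Const", "Var", "Not", "And", "Or",
    "TRUE", "FALSE", "parse_expr", "truth_table",
]


class LogicExpr:
    """Base class for Boolean expression nodes."""

    __slots__ = ()

    def support(self) -> frozenset:
        """Set of variable names the expression references."""
        raise NotImplementedError

    def evaluate(self, state: Mapping[str, int]) -> int:
        """Total, deterministic evaluation on a full state (0/1 values)."""
        raise NotImplementedError

    def restrict(self, fixed: Mapping[str, int]) -> "LogicExpr":
        """Substitute fixed values and simplify by constant folding."""
        raise NotImplementedError

    # -- conveniences -------------------------------------------------
    def is_const(self) -> bool:
        return isinstance(self, Const)

    def __and__(self, other: "LogicExpr") -> "LogicExpr":
        return And((self, other)).simplified()

    def __or__(self, other: "LogicExpr") -> "LogicExpr":
        return Or((self, other)).simplified()

    def __invert__(self) -> "LogicExpr":
        return Not(self).simplified()

    def simplified(self) -> "LogicExpr":
        return self.restrict({})

    def equivalent(self, other: "LogicExpr", max_vars: int = 20) -> bool:
        """Semantic equality by exhaustive truth-table comparison."""
        sup = sorted(self.support() | other.support())
        if len(sup) > max_vars:
            raise ValueError(f"support too large for truth-table check: {len(sup)}")
        for bits in itertools.product((0, 1), repeat=len(sup)):
            state = dict(zip(sup, bits))
            if self.evaluate(state) != other.evaluate(state):
                return False
        return True


@dataclass(frozen=True, slots=True)
class Const(LogicExpr):
    value: int  # 0 or 1

    def support(self):
        return frozenset()

    def evaluate(self, state):
        return self.value

    def restrict(self, fixed):
        return self

    def __str__(self):
        return str(self.value)


@dataclass(frozen=True, slots=True)
class Var(LogicExpr):
    name: str

    def support(self):
        return frozenset((self.name,))

    def evaluate(self, state):
        return 1 if state[self.name] else 0

    def restrict(self, fixed):
        if self.name in fixed:
            return TRUE if fixed[self.name] else FALSE
        return self

    def __str__(self):
        return self.name


@dataclass(frozen=True, slots=True)
class Not(LogicExpr):
    arg: LogicExpr

    def support(self):
        return self.arg.support()

    def evaluate(self, state):
        return 1 - self.arg.evaluate(state)

    def restrict(self, fixed):
        a = self.arg.restrict(fixed)
        if isinstance(a, Const):
            return FALSE if a.value else TRUE
        if isinstance(a, Not):  # double negation
            return a.arg
        return Not(a)

    def __str__(self):
        return f"!{_paren(self.arg, atom_only=True)}"


def _nary_restrict(cls, args, fixed, absorbing, neutral):
    out = []
    for a in args:
        r = a.restrict(fixed)
        if isinstance(r, Const):
            if r.value == absorbing:
                return Const(absorbing)
            continue  # neutral element, drop
        if isinstance(r, cls):  # flatten
            out.extend(r.args)
        else:
            out.append(r)
    dedup = []
    for a in out:
        if a not in dedup:
            dedup.append(a)
    if not dedup:
        return Const(neutral)
    if len(dedup) == 1:
        return dedup[0]
    return cls(tuple(dedup))


@dataclass(frozen=True, slots=True)
class And(LogicExpr):
    args: tuple

    def support(self):
        return frozenset().union(*(a.support() for a in self.args))

    def evaluate(self, state):
        return int(all(a.evaluate(state) for a in self.args))

    def restrict(self, fixed):
        return _nary_restrict(And, self.args, fixed, absorbing=0, neutral=1)

    def __str__(self):
        return " & ".join(_paren(a) for a in self.args)


@dataclass(frozen=True, slots=True)
class Or(LogicExpr):
    args: tuple

    def support(self):
        return frozenset().union(*(a.support() for a in self.args))

    def evaluate(self, state):
        return int(any(a.evaluate(state) for a in self.args))

    def restrict(self, fixed):
        return _nary_restrict(Or, self.args, fixed, absorbing=1, neutral=0)

    def __str__(self):
        return " | ".join(
            f"({a})" if isinstance(a, Or) else _paren(a, allow_and=True)
            for a in self.args
        )


TRUE = Const(1)
FALSE = Const(0)


def _paren(e: LogicExpr, atom_only: bool = False, allow_and: bool = False) -> str:
    if isinstance(e, (Const, Var, Not)):
        return str(e)
    if isinstance(e, And) and (allow_and or not atom_only):
        return str(e)
    return f"({e})"


def truth_table(expr: LogicExpr, order: Iterable[str]) -> int:
    """Truth table of ``expr`` over the ordered variable list, packed into an
    int (bit i = value on the assignment whose bits spell i, first variable =
    least significant bit)."""
    order = list(order)
    tt = 0
    for i in range(2 ** len(order)):
        state = {v: (i >> j) & 1 for j, v in enumerate(order)}
        if expr.evaluate(state):
            tt |= 1 << i
    return tt


# ---------------------------------------------------------------------------
# concrete syntax
# ---------------------------------------------------------------------------

_TOKEN = re.compile(r"\s*(?:(?P<id>[A-Za-z_][\w/:.\-]*)|(?P<const>[01])"
                    r"|(?P<op>[!&|()]))")


def _tokenize(text: str):
    pos, out = 0, []
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if not m:
            if text[pos:].strip() == "":
                break
            raise ParseError(f"bad token at position {pos}: {text[pos:pos + 10]!r}")
        pos = m.end()
        if m.lastgroup == "id":
            out.append(("id", m.group("id")))
        elif m.lastgroup == "const":
            out.append(("const", int(m.group("const"))))
        else:
            out.append((m.group("op"), None))
    return out


def parse_expr(text: str) -> LogicExpr:
    """Parse the small infix syntax into a :class:`LogicExpr`."""
    tokens = _tokenize(text)
    pos = 0

    def peek():
        return tokens[pos][0] if pos < len(tokens) else None

    def expect(kind):
        nonlocal pos
        if peek() != kind:
            raise ParseError(f"expected {kind!r} at token {pos} in {text!r}")
        pos += 1

    def atom():
        nonlocal pos
        k = peek()
        if k == "(":
            expect("(")
            e = disj()
            expect(")")
            return e
        if k == "!":
            expect("!")
            return Not(atom()).simplified()
        if k == "id":
            name = tokens[pos][1]
            pos += 1
            return Var(name)
        if k == "const":
            val = tokens[pos][1]
            pos += 1
            return Const(val)
        raise ParseError(f"unexpected token {k!r} in {text!r}")

    def conj():
        e = atom()
        while peek() == "&":
            expect("&")
            e = And((e, atom())).simplified()
        return e

    def disj():
        e = conj()
        while peek() == "|":
            expect("|")
            e = Or((e, conj())).simplified()
        return e

    e = disj()
    if pos != len(tokens):
        raise ParseError(f"trailing tokens in {text!r}")
    return e
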