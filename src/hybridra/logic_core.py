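"""Value propagation, network reduction and minimal trap spaces.

A *partial state* assigns 0, 1 or FREE to each component; it denotes the
subspace of full Boolean states agreeing with its fixed values.  A *trap
space* is a subspace closed under asynchronous (single-component) updates:
once the dynamics enters it, it cannot escape.  Minimal trap spaces — those
containing no strictly smaller trap space — approximate the attractors of
the asynchronous dynamics and are the quantity this module computes.

Two independent routes are provided:

* :func:`minimal_trapspaces` — the production algorithm.  It percolates
  constants, computes positive and negative prime implicants of every
  update rule (Quine–McCluskey) and searches for self-sustaining literal
  sets (stable motifs), recursing through the motif-succession tree.
* :func:`brute_force_minimal_trapspaces` — an exhaustive enumerator over
  all 3^n partial states, used as the verification oracle on small
  networks.

Both return the same lexicographically ordered result on any network small
enough for the oracle; the test suite pins this equivalence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .errors import BudgetExceededError, ValidationError
from .expr import Const, LogicExpr, Var
from .qual_io import BooleanNetwork, Condition

__all__ = [
    "FREE", "PartialState", "TrapSpace",
    "propagate", "reduce_network", "prime_implicants",
    "is_trapspace", "minimal_trapspaces", "brute_force_minimal_trapspaces",
    "trapspaces_to_frame",
]

FREE = "*"


@dataclass(frozen=True)
class PartialState:
    """A ternary assignment component -> {0, 1, FREE}; FREE entries are
    implicit (absent from the fixed mapping)."""

    _items: tuple

    def __init__(self, fixed: Mapping[str, int] = ()):
        items = tuple(sorted(dict(fixed).items()))
        for k, v in items:
            if v not in (0, 1):
                raise ValidationError(f"partial state value for {k!r} must be 0/1")
        object.__setattr__(self, "_items", items)

    @property
    def fixed(self) -> dict:
        return dict(self._items)

    @property
    def n_fixed(self) -> int:
        return len(self._items)

    def get(self, component: str):
        return dict(self._items).get(component, FREE)

    def __getitem__(self, component: str):
        return self.get(component)

    def literals(self) -> frozenset:
        return frozenset(self._items)

    def count(self, value: int) -> int:
        return sum(1 for _, v in self._items if v == value)

    def is_within(self, other: "PartialState") -> bool:
        """True iff this subspace is contained in ``other`` (this fixes a
        superset of other's literals, consistently)."""
        return self.literals() >= other.literals()

    def sort_key(self, components: Iterable[str]):
        rank = {0: 0, 1: 1}
        f = self.fixed
        return tuple(rank.get(f.get(c, FREE), 2) for c in components)

    def __repr__(self):
        inner = ", ".join(f"{k}={v}" for k, v in self._items)
        return f"PartialState({inner})"


@dataclass(frozen=True)
class TrapSpace:
    """A partial state closed under asynchronous dynamics."""

    state: PartialState
    minimal: bool = False

    def get(self, component: str):
        return self.state.get(component)


def _as_fixed_mapping(net: BooleanNetwork, fixed) -> dict:
    if isinstance(fixed, Condition):
        fixed.resolve(net)
        return dict(fixed.assignments)
    if isinstance(fixed, PartialState):
        fixed = fixed.fixed
    fixed = dict(fixed)
    unknown = set(fixed) - set(net.components)
    if unknown:
        raise ValidationError(f"fixed components not in network: {sorted(unknown)}")
    for k, v in fixed.items():
        if v not in (0, 1):
            raise ValidationError(f"fixed value for {k!r} must be 0/1, got {v!r}")
    return fixed


def propagate(net: BooleanNetwork, fixed) -> PartialState:
    """Least fixpoint of iterative constant propagation (percolation).

    Starting from the caller's fixed assignments, repeatedly fix any
    component whose rule evaluates to a constant under the current partial
    assignment, until stable.  Clamped components keep their clamped value
    regardless of their own rule; propagation only ever adds assignments,
    so no contradiction can arise past the caller's input (conflicting
    caller inputs are rejected when conditions are merged).
    """
    state = _as_fixed_mapping(net, fixed)
    pending = [c for c in net.components if c not in state]
    changed = True
    while changed:
        changed = False
        still = []
        for c in pending:
            r = net.rules[c].restrict(state)
            if isinstance(r, Const):
                state[c] = r.value
                changed = True
            else:
                still.append(c)
        pending = still
    return PartialState(state)


def reduce_network(net: BooleanNetwork, fixed) -> BooleanNetwork:
    """Substitute fixed values into every rule and simplify.

    Fixed components become constant-rule components; the rules of the
    remaining free components reference only free variables.
    """
    if isinstance(fixed, PartialState):
        fixed = fixed.fixed
    fixed = _as_fixed_mapping(net, fixed)
    new_rules = {}
    for c in net.components:
        if c in fixed:
            new_rules[c] = Const(fixed[c])
        else:
            new_rules[c] = net.rules[c].restrict(fixed)
    return BooleanNetwork(net.components, new_rules, net.names)


# ---------------------------------------------------------------------------
# prime implicants (Quine-McCluskey)
# ---------------------------------------------------------------------------

def prime_implicants(expr: LogicExpr, value: int, max_support: int = 16) -> list:
    """All prime implicants of ``expr == value``.

    Each implicant is a minimal literal conjunction forcing the rule to
    ``value``, returned as a dict ``variable -> 0/1``; the empty dict is
    the vacuous implicant of a constant function.  Computed by
    Quine-McCluskey over the expression's support.
    """
    support = sorted(expr.support())
    n = len(support)
    if n > max_support:
        raise BudgetExceededError(
            f"prime-implicant support {n} exceeds cap {max_support}")
    minterms = []
    for i in range(2 ** n):
        state = {v: (i >> j) & 1 for j, v in enumerate(support)}
        if expr.evaluate(state) == value:
            minterms.append(i)
    primes = _quine_mccluskey(minterms, n)
    out = []
    for care, bits in sorted(primes):
        out.append({support[j]: (bits >> j) & 1
                    for j in range(n) if care & (1 << j)})
    return out


def _quine_mccluskey(minterms, n):
    """Classic QM merge: returns a set of (care_mask, bits) cubes."""
    if not minterms:
        return set()
    if n == 0:
        return {(0, 0)}
    terms = {(2 ** n - 1, m) for m in minterms}
    primes = set()
    while terms:
        merged = set()
        nxt = set()
        by_care = {}
        for t in terms:
            by_care.setdefault(t[0], []).append(t)
        for care, group in by_care.items():
            group = sorted(group)
            for i, t1 in enumerate(group):
                for t2 in group[i + 1:]:
                    diff = t1[1] ^ t2[1]
                    if diff and (diff & (diff - 1)) == 0:
                        nxt.add((care & ~diff, t1[1] & ~diff))
                        merged.add(t1)
                        merged.add(t2)
        primes |= terms - merged
        terms = nxt
    return primes


# ---------------------------------------------------------------------------
# trap-space checks and computation
# ---------------------------------------------------------------------------

def is_trapspace(net: BooleanNetwork, ps: PartialState,
                 budget: int = 16) -> bool:
    """Exhaustive closure check: true iff from every full state inside the
    subspace, every asynchronous single-component update stays inside.

    Equivalent formulation used here: for every fixed component ``x = v``,
    the rule of ``x`` restricted to the subspace is constantly ``v``.
    Raises :class:`BudgetExceededError` when a restricted rule still
    depends on more than ``budget`` free variables.
    """
    fixed = ps.fixed
    unknown = set(fixed) - set(net.components)
    if unknown:
        raise ValidationError(f"partial state mentions unknown components: {sorted(unknown)}")
    for c, v in fixed.items():
        r = net.rules[c].restrict(fixed)
        if isinstance(r, Const):
            if r.value != v:
                return False
            continue
        sup = sorted(r.support())
        if len(sup) > budget:
            raise BudgetExceededError(
                f"exhaustive closure check for {c!r} needs {len(sup)} free "
                f"variables, budget is {budget}")
        for bits in itertools.product((0, 1), repeat=len(sup)):
            if r.evaluate(dict(zip(sup, bits))) != v:
                return False
    return True


def brute_force_minimal_trapspaces(net: BooleanNetwork,
                                   max_components: int = 10) -> list:
    """Verification oracle: enumerate all 3^n partial states, keep the trap
    spaces, and filter to the minimal ones by literal-set containment.

    Independent of :func:`minimal_trapspaces` (no prime implicants, no
    motif search); capped at ``max_components`` components.
    """
    comps = list(net.components)
    n = len(comps)
    if n > max_components:
        raise BudgetExceededError(
            f"{n} components exceeds the exhaustive cap {max_components}")

    traps = []
    for values in itertools.product((0, 1, None), repeat=n):
        fixed = {c: v for c, v in zip(comps, values) if v is not None}
        ok = True
        for c, v in fixed.items():
            r = net.rules[c].restrict(fixed)
            if isinstance(r, Const):
                if r.value != v:
                    ok = False
                    break
                continue
            sup = sorted(r.support())
            for bits in itertools.product((0, 1), repeat=len(sup)):
                if r.evaluate(dict(zip(sup, bits))) != v:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            traps.append(frozenset(fixed.items()))

    # minimal trap space = maximal literal set among traps
    traps.sort(key=len, reverse=True)
    maximal = []
    for t in traps:
        if not any(m > t for m in maximal):
            maximal.append(t)
    states = [PartialState(dict(t)) for t in maximal]
    states.sort(key=lambda s: s.sort_key(comps))
    return [TrapSpace(s, minimal=True) for s in states]


def _stable_motifs(net: BooleanNetwork, free: list, counter: list,
                   budget: int) -> list:
    """Minimal nonempty consistent self-sustaining literal sets among the
    free components: every literal in the set is backed by a prime
    implicant lying entirely inside the set."""
    pis = {}
    for c in free:
        for v in (0, 1):
            pis[(c, v)] = prime_implicants(net.rules[c], v)

    motifs = set()

    def extend(assign: dict, pending: frozenset):
        counter[0] += 1
        if counter[0] > budget:
            raise BudgetExceededError(
                f"trap-space search exceeded its node budget ({budget}); "
                "raise the budget to continue")
        if not pending:
            motifs.add(frozenset(assign.items()))
            return
        lit = min(pending)
        c, v = lit
        for pi in pis[(c, v)]:
            if any(assign.get(x, b) != b for x, b in pi.items()):
                continue  # inconsistent choice
            new_assign = dict(assign)
            new_pending = set(pending)
            new_pending.discard(lit)
            for x, b in pi.items():
                if x not in assign:
                    new_assign[x] = b
                    new_pending.add((x, b))
            extend(new_assign, frozenset(new_pending))

    for c in free:
        for v in (0, 1):
            extend({c: v}, frozenset(((c, v),)))

    minimal = [m for m in motifs if not any(o < m for o in motifs)]
    minimal.sort(key=lambda m: sorted(m))
    return [dict(m) for m in minimal]


def minimal_trapspaces(net: BooleanNetwork, budget: int = 500_000) -> list:
    """The complete set of minimal trap spaces, in lexicographic order.

    Algorithm: percolate constants, compute stable motifs of the reduced
    network from the prime implicants of each rule, and recurse into every
    motif (motif-succession search).  A branch with no remaining motif has
    reached a minimal trap space.  ``budget`` caps the total number of
    search nodes; exceeding it raises :class:`BudgetExceededError` rather
    than returning a silent partial answer.
    """
    counter = [0]
    results = set()
    seen = set()

    def rec(fixed: dict):
        ps = propagate(net, fixed)
        key = ps.literals()
        if key in seen:
            return
        seen.add(key)
        red = reduce_network(net, ps)
        free = [c for c in net.components if ps.get(c) is FREE]
        motifs = _stable_motifs(red, free, counter, budget)
        if not motifs:
            results.add(key)
            return
        for m in motifs:
            merged = dict(ps.fixed)
            merged.update(m)
            rec(merged)

    rec({})
    states = [PartialState(dict(t)) for t in results]
    states.sort(key=lambda s: s.sort_key(net.components))
    return [TrapSpace(s, minimal=True) for s in states]


def trapspaces_to_frame(trapspaces: list, net: BooleanNetwork) -> pd.DataFrame:
    """Component x trap-space matrix with 0/1/* entries (one column per
    trap space, in the deterministic output order)."""
    cols = {}
    for i, ts in enumerate(trapspaces):
        cols[str(i)] = [ts.get(c) for c in net.components]
    return pd.DataFrame(cols, index=list(net.components))
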