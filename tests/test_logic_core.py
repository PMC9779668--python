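"""Value propagation, reduction, prime implicants and trap spaces."""

import itertools

import pytest

from hybridra import (BooleanNetwork, Condition, PartialState,
                      brute_force_minimal_trapspaces, is_trapspace,
                      minimal_trapspaces, prime_implicants, propagate,
                      reduce_network)
from hybridra.errors import BudgetExceededError, ValidationError
from hybridra.expr import Const, Not, Var, parse_expr, truth_table
from hybridra.fixtures import random_boolean_network


def chain():
    return BooleanNetwork(("A", "B", "C"),
                          {"A": Var("A"), "B": Var("A"), "C": Var("B")})


# --- propagation -------------------------------------------------------

def test_linear_percolation():
    ps = propagate(chain(), {"A": 1})
    assert ps.fixed == {"A": 1, "B": 1, "C": 1}


def test_empty_condition_fixes_only_constants():
    net = BooleanNetwork(("A", "B"), {"A": Const(1), "B": Var("A")})
    ps = propagate(net, {})
    assert ps.fixed == {"A": 1, "B": 1}
    free_net = chain()
    assert propagate(free_net, {}).fixed == {}


def test_clamp_overrides_rule():
    """A clamped component keeps its clamped value even when its own rule
    disagrees (the condition is an external clamp, not a seed)."""
    net = BooleanNetwork(("A", "B"), {"A": Const(1), "B": Var("A")})
    ps = propagate(net, {"A": 0})
    assert ps.fixed == {"A": 0, "B": 0}


def test_propagate_rejects_unknown_component():
    with pytest.raises(ValidationError):
        propagate(chain(), {"Z": 1})


@pytest.mark.parametrize("seed", range(20))
def test_propagate_idempotent_and_monotone(seed):
    import random
    rng = random.Random(seed)
    net = random_boolean_network(9, 3, seed)
    comps = list(net.components)
    base = {c: rng.randint(0, 1) for c in rng.sample(comps, 3)}
    p1 = propagate(net, base)
    # idempotence
    assert propagate(net, p1).literals() == p1.literals()
    # monotone under consistent extension by already-derived literals
    extra = dict(list(p1.fixed.items())[:2])
    assert propagate(net, {**base, **extra}).literals() == p1.literals()
    # monotone under extension on components the fixpoint left free
    free = [c for c in comps if p1.get(c) == "*"]
    if free:
        grown = {**base, free[0]: rng.randint(0, 1)}
        assert propagate(net, grown).literals() >= p1.literals()


# --- reduction ---------------------------------------------------------

def test_reduce_chain():
    red = reduce_network(chain(), PartialState({"A": 1}))
    assert red.rules["B"] == Const(1)
    # C still depends on B until propagation is applied first
    red2 = reduce_network(chain(), propagate(chain(), {"A": 1}))
    assert red2.rules["C"] == Const(1)


def test_reduce_identity_on_empty():
    net = chain()
    red = reduce_network(net, PartialState({}))
    assert red.rules == net.rules


@pytest.mark.parametrize("seed", range(10))
def test_reduce_preserves_restricted_truth_tables(seed):
    """Each reduced rule equals the original rule restricted to the fixed
    assignment, checked exhaustively over the remaining support."""
    import random
    rng = random.Random(seed + 1000)
    net = random_boolean_network(8, 3, seed)
    fixed = {c: rng.randint(0, 1) for c in rng.sample(list(net.components), 3)}
    red = reduce_network(net, fixed)
    for c in net.components:
        if c in fixed:
            assert red.rules[c] == Const(fixed[c])
            continue
        sup = sorted(net.rules[c].support() - set(fixed))
        for bits in itertools.product((0, 1), repeat=len(sup)):
            state = {**fixed, **dict(zip(sup, bits))}
            assert red.rules[c].evaluate(state) == net.rules[c].evaluate(state)


# --- prime implicants --------------------------------------------------

@pytest.mark.parametrize("text,value,expected", [
    ("A & B", 1, [{"A": 1, "B": 1}]),
    ("A & B", 0, [{"A": 0}, {"B": 0}]),
    ("A | B", 1, [{"A": 1}, {"B": 1}]),
    ("!A", 1, [{"A": 0}]),
    ("A & !A", 1, []),
    ("A | !A", 1, [{}]),
])
def test_prime_implicants_known_cases(text, value, expected):
    got = prime_implicants(parse_expr(text), value)
    assert sorted(got, key=sorted) == sorted(expected, key=sorted)


@pytest.mark.parametrize("seed", range(10))
def test_prime_implicants_cover_and_force(seed):
    """Every implicant forces the target value; the implicants jointly
    cover every satisfying assignment (soundness + completeness)."""
    net = random_boolean_network(6, 4, seed)
    for c in net.components:
        e = net.rules[c]
        sup = sorted(e.support())
        for value in (0, 1):
            pis = prime_implicants(e, value)
            for pi in pis:
                free = [v for v in sup if v not in pi]
                for bits in itertools.product((0, 1), repeat=len(free)):
                    state = {**pi, **dict(zip(free, bits))}
                    assert e.evaluate(state) == value
            for bits in itertools.product((0, 1), repeat=len(sup)):
                state = dict(zip(sup, bits))
                if e.evaluate(state) == value:
                    assert any(all(state[k] == v for k, v in pi.items())
                               for pi in pis)


# --- trap spaces -------------------------------------------------------

def test_full_space_is_trapped():
    assert is_trapspace(chain(), PartialState({}))


def test_negative_self_loop():
    net = BooleanNetwork(("A",), {"A": Not(Var("A"))})
    assert not is_trapspace(net, PartialState({"A": 0}))
    spaces = minimal_trapspaces(net)
    assert len(spaces) == 1 and spaces[0].state.fixed == {}


def test_positive_loop_two_fixed_points():
    net = BooleanNetwork(("A", "B"), {"A": Var("B"), "B": Var("A")})
    spaces = brute_force_minimal_trapspaces(net)
    assert [t.state.fixed for t in spaces] == [{"A": 0, "B": 0},
                                               {"A": 1, "B": 1}]


def test_independent_identity_nodes_product():
    net = BooleanNetwork(("A", "B"), {"A": Var("A"), "B": Var("B")})
    spaces = brute_force_minimal_trapspaces(net)
    assert [t.state.fixed for t in spaces] == [
        {"A": 0, "B": 0}, {"A": 0, "B": 1}, {"A": 1, "B": 0}, {"A": 1, "B": 1}]


def test_is_trapspace_budget():
    net = BooleanNetwork(("A", "B", "C"),
                         {"A": parse_expr("B | C"), "B": Var("B"), "C": Var("C")})
    with pytest.raises(BudgetExceededError):
        is_trapspace(net, PartialState({"A": 1}), budget=1)


def test_minimal_trapspaces_budget_error():
    net = random_boolean_network(10, 3, seed=0)
    with pytest.raises(BudgetExceededError):
        minimal_trapspaces(net, budget=2)


@pytest.mark.parametrize("seed", range(30))
def test_oracle_equivalence_small_random_nets(seed):
    """Production algorithm vs exhaustive enumerator on 6-node networks."""
    net = random_boolean_network(6, 3, seed)
    fast = [t.state.literals() for t in minimal_trapspaces(net)]
    slow = [t.state.literals() for t in brute_force_minimal_trapspaces(net)]
    assert fast == slow


@pytest.mark.parametrize("seed", range(10))
def test_reported_trapspaces_are_closed_and_incomparable(seed):
    net = random_boolean_network(8, 3, seed + 200)
    spaces = minimal_trapspaces(net)
    lits = [t.state.literals() for t in spaces]
    for t in spaces:
        assert is_trapspace(net, t.state)
    for a, b in itertools.combinations(lits, 2):
        assert not (a < b or b < a)


def test_determinism_across_runs():
    net = random_boolean_network(8, 3, seed=7)
    a = [t.state.fixed for t in minimal_trapspaces(net)]
    b = [t.state.fixed for t in minimal_trapspaces(net)]
    assert a == b


def test_trapspace_frame_layout(toy_warburg):
    from hybridra import trapspaces_to_frame
    net = toy_warburg.net
    ps = propagate(net, toy_warburg.condition)
    red = reduce_network(net, ps)
    spaces = minimal_trapspaces(red)
    frame = trapspaces_to_frame(spaces, red)
    assert list(frame.index) == list(net.components)
    assert frame.shape[1] == len(spaces)
    assert set(frame.values.ravel()) <= {0, 1, "*"}
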