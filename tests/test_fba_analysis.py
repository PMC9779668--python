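"""FBA solving, ATP-source fractions, C-flux tables, fold comparisons."""

import cobra
import numpy as np
import pytest
from cobra.util.array import create_stoichiometric_matrix

from hybridra import atp_fractions, cflux_report, compare_fluxes, solve_fba
from hybridra.bridge import ConstraintSet
from hybridra.errors import (FormulaError, UndefinedFractionError,
                             ValidationError)
from hybridra.fba_analysis import FluxSolution
from hybridra.metab_io import ObjectiveSpec, wrap_cobra_model

from conftest import vertex_enumeration_max


def _chain_model(cap=10.0):
    """uptake(cap) -> A -> ATP-producing terminal reaction."""
    m = cobra.Model("chain")
    a = cobra.Metabolite("a_c", formula="C2", compartment="c")
    atp = cobra.Metabolite("atp_c", formula="HO3P", compartment="c")
    ex = cobra.Reaction("EX_a", lower_bound=-cap, upper_bound=1000)
    r1 = cobra.Reaction("R_MAKE", lower_bound=0, upper_bound=1000)
    dm = cobra.Reaction("DM_atp", lower_bound=0, upper_bound=1000)
    m.add_reactions([ex, r1, dm])
    ex.add_metabolites({a: -1})
    r1.add_metabolites({a: -1, atp: 1})
    dm.add_metabolites({atp: -1})
    return wrap_cobra_model(m)


def test_bound_limited_chain():
    model = _chain_model(cap=10.0)
    sol = solve_fba(model, None, ObjectiveSpec({"R_MAKE": 1.0}))
    assert sol.optimal
    assert sol.objective_value == pytest.approx(10.0, abs=1e-9)


def test_solution_satisfies_mass_balance(toy_warburg):
    sol = solve_fba(toy_warburg.model, None, toy_warburg.objective)
    S = create_stoichiometric_matrix(toy_warburg.model.cobra_model)
    v = np.array([sol.fluxes[r.id] for r in toy_warburg.model.reactions])
    assert np.max(np.abs(S @ v)) < 1e-6


def test_zeroed_reactions_carry_zero_flux(toy_warburg):
    cs = ConstraintSet({"R_PDHm"}, {"R_PDHm": [("PDHm", "enzyme-catalyzed")]})
    sol = solve_fba(toy_warburg.model, cs, toy_warburg.objective)
    assert abs(sol.fluxes["R_PDHm"]) <= 1e-9
    assert sol.metadata["n_constraints"] == 1


def test_lp_matches_vertex_enumeration_oracle(toy_warburg):
    """Objective optimum equals exhaustive vertex enumeration on small
    sub-LPs (8 reactions or fewer)."""
    model = _chain_model(cap=7.5)
    obj = ObjectiveSpec({"R_MAKE": 1.0})
    sol = solve_fba(model, None, obj)
    S = create_stoichiometric_matrix(model.cobra_model)
    rids = [r.id for r in model.reactions]
    lb = [model.reaction(r).lower_bound for r in rids]
    ub = [model.reaction(r).upper_bound for r in rids]
    c = [obj.terms.get(r, 0.0) for r in rids]
    assert sol.objective_value == pytest.approx(
        vertex_enumeration_max(S, lb, ub, c), abs=1e-8)


def test_infeasible_reported_not_fabricated(toy_warburg):
    model = toy_warburg.model.copy()
    model.reaction("DM_atp_c").lower_bound = 5.0  # demand that must be met
    cs = ConstraintSet({"R_HK", "R_TCA"},
                       {"R_HK": [("x", "enzyme-catalyzed")],
                        "R_TCA": [("x", "enzyme-catalyzed")]})
    sol = solve_fba(model, cs, toy_warburg.objective)
    assert sol.status == "infeasible"
    assert sol.fluxes == {}


# --- ATP fractions -----------------------------------------------------

def test_atp_fraction_pure_oxphos():
    obj = ObjectiveSpec({"R_G": 1.0, "R_O": 1.0})
    sol = FluxSolution({"R_G": 0.0, "R_O": 4.0}, 4.0, "optimal")
    rep = atp_fractions(sol, obj, {"R_G"}, {"R_O"})
    assert rep.glycolysis_pct == pytest.approx(0.0)
    assert rep.oxphos_pct == pytest.approx(100.0)


def test_atp_fractions_sum_to_100(toy_warburg):
    sol = solve_fba(toy_warburg.model, None, toy_warburg.objective)
    rep = atp_fractions(sol, toy_warburg.objective,
                        toy_warburg.glycolytic_terms, toy_warburg.oxphos_terms)
    assert rep.glycolysis_pct + rep.oxphos_pct == pytest.approx(100.0, abs=1e-6)


def test_atp_fractions_undefined_at_zero():
    obj = ObjectiveSpec({"R_G": 1.0})
    sol = FluxSolution({"R_G": 0.0}, 0.0, "optimal")
    with pytest.raises(UndefinedFractionError):
        atp_fractions(sol, obj, {"R_G"}, set())


def test_atp_fraction_groups_must_cover_objective():
    obj = ObjectiveSpec({"R_G": 1.0, "R_O": 1.0})
    sol = FluxSolution({"R_G": 1.0, "R_O": 1.0}, 2.0, "optimal")
    with pytest.raises(ValidationError):
        atp_fractions(sol, obj, {"R_G"}, set())


# --- C-flux ------------------------------------------------------------

def test_cflux_glucose_co2_balance():
    """1 glucose in (6 C), 6 CO2 out: both sides 100%, carbon conserved."""
    m = cobra.Model("cb")
    glc = cobra.Metabolite("glc_e", formula="C6H12O6", compartment="e")
    co2 = cobra.Metabolite("co2_e", formula="CO2", compartment="e")
    ex_g = cobra.Reaction("EX_glc", lower_bound=-1, upper_bound=0)
    ex_c = cobra.Reaction("EX_co2", lower_bound=0, upper_bound=10)
    burn = cobra.Reaction("R_BURN", lower_bound=0, upper_bound=10)
    m.add_reactions([ex_g, ex_c, burn])
    ex_g.add_metabolites({glc: -1})
    ex_c.add_metabolites({co2: -1})
    burn.add_metabolites({glc: -1, co2: 6})
    model = wrap_cobra_model(m)
    sol = FluxSolution({"EX_glc": -1.0, "EX_co2": 6.0, "R_BURN": 1.0},
                       1.0, "optimal")
    rep = cflux_report(sol, model)
    assert rep.uptake == {"EX_glc": pytest.approx(100.0)}
    assert rep.secretion == {"EX_co2": pytest.approx(100.0)}
    assert rep.uptake_carbon == pytest.approx(rep.secretion_carbon)


def test_cflux_empty_when_no_carbon_crosses(toy_warburg):
    fluxes = {r.id: 0.0 for r in toy_warburg.model.reactions}
    rep = cflux_report(FluxSolution(fluxes, 0.0, "optimal"), toy_warburg.model)
    assert rep.uptake == {} and rep.secretion == {}


def test_cflux_refuses_carbon_unknown_boundary():
    m = cobra.Model("cu")
    x = cobra.Metabolite("x_e", compartment="e")  # no formula
    ex = cobra.Reaction("EX_x", lower_bound=-5, upper_bound=5)
    m.add_reactions([ex])
    ex.add_metabolites({x: -1})
    model = wrap_cobra_model(m)
    sol = FluxSolution({"EX_x": -1.0}, 0.0, "optimal")
    with pytest.raises(FormulaError, match="x_e"):
        cflux_report(sol, model)


def test_cflux_sides_sum_to_100(toy_warburg, toy_control):
    for pair in (toy_warburg, toy_control):
        from hybridra.pipeline import analyze_condition
        res = analyze_condition(pair.net, pair.condition, pair.model,
                                pair.mapping, pair.objective,
                                pair.glycolytic_terms, pair.oxphos_terms)
        for side in (res.cflux.uptake, res.cflux.secretion):
            assert sum(side.values()) == pytest.approx(100.0, abs=1e-6)


# --- fold comparisons --------------------------------------------------

def _sol(**fluxes):
    return FluxSolution(dict(fluxes), 0.0, "optimal")


def test_fold_change_categories():
    a = _sol(R1=1.0, R2=1.0, R3=0.0, R4=2.0, R5=0.5)
    b = _sol(R1=3.0, R2=1.5, R3=2.0, R4=0.0, R5=0.1)
    by_rxn = {c.reaction: c for c in compare_fluxes(a, b)}
    assert by_rxn["R1"].category == "increased"      # 3-fold
    assert "R2" not in by_rxn                         # 1.5-fold, below threshold
    assert by_rxn["R3"].category == "switched-on"
    assert by_rxn["R4"].category == "switched-off"
    assert by_rxn["R5"].category == "decreased"       # 5-fold down


def test_fold_change_symmetric_under_swap():
    a = _sol(R1=1.0, R3=0.0)
    b = _sol(R1=3.0, R3=2.0)
    fwd = {c.reaction: c.category for c in compare_fluxes(a, b)}
    rev = {c.reaction: c.category for c in compare_fluxes(b, a)}
    swap = {"increased": "decreased", "decreased": "increased",
            "switched-on": "switched-off", "switched-off": "switched-on"}
    assert rev == {r: swap[c] for r, c in fwd.items()}


def test_fold_changes_sorted_descending():
    a = _sol(R1=1.0, R2=1.0)
    b = _sol(R1=3.0, R2=10.0)
    folds = [c.fold for c in compare_fluxes(a, b)]
    assert folds == sorted(folds, reverse=True)
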