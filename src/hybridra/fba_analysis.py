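"""Flux balance analysis and downstream reports.

The LP — maximize a weighted sum of ATP-producing reaction fluxes subject
to steady-state mass balance S·v = 0 and flux bounds — is solved through
cobrapy/optlang (GLPK).  On top of the optimal flux vector this module
computes:

* ATP-source fractions: the share of the objective contributed by the
  glycolytic terms versus the oxidative-phosphorylation term;
* C-flux tables: carbon-atom-weighted boundary fluxes, expressed per
  reaction as a percentage of total carbon influx (uptake side) and total
  carbon efflux (secretion side);
* fold-change comparisons between two conditions (default threshold:
  2-fold), with switched-on/off classification for fluxes crossing the
  activity epsilon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .bridge import ConstraintSet
from .errors import (FormulaError, UndefinedFractionError, ValidationError)
from .metab_io import MetabolicModel, ObjectiveSpec, classify_boundary

logger = logging.getLogger("hybridra.fba")

__all__ = [
    "FluxSolution", "AtpReport", "CFluxReport", "FluxChange",
    "solve_fba", "atp_fractions", "cflux_report", "compare_fluxes",
]

FEASIBILITY_TOL = 1e-9


@dataclass
class FluxSolution:
    """An FBA result: flux per reaction, objective value and solver status
    (``optimal``/``infeasible``/``unbounded``), plus solver metadata."""

    fluxes: dict
    objective_value: float
    status: str
    metadata: dict = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


@dataclass
class AtpReport:
    """ATP-source split of the objective, in percent."""

    glycolysis_pct: float
    oxphos_pct: float
    terms: dict  # reaction -> absolute contribution (weight * flux)


@dataclass
class CFluxReport:
    """Carbon-weighted boundary flux percentages, per side."""

    uptake: dict     # reaction -> % of total carbon influx
    secretion: dict  # reaction -> % of total carbon efflux
    uptake_carbon: float = 0.0     # total influx, carbon atoms x flux units
    secretion_carbon: float = 0.0


@dataclass
class FluxChange:
    reaction: str
    flux_a: float
    flux_b: float
    category: str  # increased | decreased | switched-on | switched-off
    fold: float


def solve_fba(model: MetabolicModel, constraints: ConstraintSet | None,
              objective: ObjectiveSpec, parsimonious: bool = False,
              ) -> FluxSolution:
    """Maximize the objective under mass balance, bounds and the zero-flux
    constraint set.

    Zeroed reactions get lb = ub = 0 (full shutdown, both directions).
    When ``parsimonious`` is set, a deterministic secondary minimization of
    total absolute flux is applied at the fixed optimum (pFBA); default is
    plain FBA, whose objective value — and hence every objective-derived
    fraction — is unique even when the flux vector is degenerate.
    """
    objective.validate(model)
    constraints = constraints or ConstraintSet.empty()
    m = model.cobra_model.copy()
    for rid in constraints.zeroed:
        if rid not in m.reactions:
            raise ValidationError(f"constraint names unknown reaction {rid!r}")
        rxn = m.reactions.get_by_id(rid)
        rxn.lower_bound = 0.0
        rxn.upper_bound = 0.0
    m.objective = {m.reactions.get_by_id(r): w for r, w in objective.terms.items()}
    m.objective_direction = "max"
    m.solver.configuration.tolerances.feasibility = FEASIBILITY_TOL

    if parsimonious:
        from cobra.flux_analysis import pfba
        try:
            sol = pfba(m)
            status = "optimal"
            objective_value = sum(w * sol.fluxes[r]
                                  for r, w in objective.terms.items())
        except Exception:
            sol, status, objective_value = None, "infeasible", float("nan")
    else:
        sol = m.optimize()
        status = sol.status
        objective_value = sol.objective_value if status == "optimal" else float("nan")

    fluxes = dict(sol.fluxes) if sol is not None and status == "optimal" else {}
    # zeroed reactions must be exactly zero, not just within solver slack
    for rid in constraints.zeroed:
        if rid in fluxes:
            fluxes[rid] = 0.0
    meta = {
        "solver": str(type(m.solver).__module__),
        "feasibility_tolerance": FEASIBILITY_TOL,
        "parsimonious": parsimonious,
        "n_constraints": len(constraints),
        "objective": objective.label,
    }
    if status != "optimal":
        logger.warning("FBA did not reach an optimum: status=%s", status)
    return FluxSolution(fluxes, objective_value, status, meta)


def atp_fractions(sol: FluxSolution, objective: ObjectiveSpec,
                  glycolytic_terms, oxphos_terms) -> AtpReport:
    """Percent of total ATP production from the glycolytic versus the
    OXPHOS objective terms (positive contributions of the named terms)."""
    glycolytic_terms = set(glycolytic_terms)
    oxphos_terms = set(oxphos_terms)
    if glycolytic_terms | oxphos_terms != set(objective.terms):
        raise ValidationError(
            "glycolytic + OXPHOS term groups must cover exactly the objective terms")
    if not sol.optimal:
        raise ValidationError(f"solution is not optimal (status={sol.status})")

    contributions = {r: max(objective.terms[r] * sol.fluxes.get(r, 0.0), 0.0)
                     for r in objective.terms}
    total = sum(contributions.values())
    if total <= 0:
        raise UndefinedFractionError(
            "objective value is 0: ATP-source fractions are undefined")
    gly = 100.0 * sum(contributions[r] for r in glycolytic_terms) / total
    oxp = 100.0 * sum(contributions[r] for r in oxphos_terms) / total
    return AtpReport(gly, oxp, contributions)


def cflux_report(sol: FluxSolution, model: MetabolicModel,
                 zero_tol: float = 1e-9) -> CFluxReport:
    """Carbon-flux percentages per boundary reaction.

    Each boundary reaction carrying a carbon-bearing metabolite
    contributes ``carbons x |flux|``; uptake and secretion sides are
    normalized to 100% separately.  A carbon-unknown metabolite crossing
    the boundary is an error.
    """
    if not sol.optimal:
        raise ValidationError(f"solution is not optimal (status={sol.status})")
    uptake_ids, secretion_ids = classify_boundary(model, sol.fluxes, zero_tol)

    def side(ids):
        weights = {}
        for rid in sorted(ids):
            mid = model.boundary_metabolite(rid)
            info = model.metabolites[mid]
            if info.carbons is None:
                raise FormulaError(
                    f"metabolite {mid!r} crosses the boundary ({rid}) but has "
                    "no parseable elemental formula; cannot count carbon")
            if info.carbons == 0:
                continue
            weights[rid] = info.carbons * abs(sol.fluxes[rid])
        total = sum(weights.values())
        pct = ({rid: 100.0 * w / total for rid, w in weights.items()}
               if total > 0 else {})
        return pct, total

    up_pct, up_total = side(uptake_ids)
    sec_pct, sec_total = side(secretion_ids)
    return CFluxReport(up_pct, sec_pct, up_total, sec_total)


def compare_fluxes(a: FluxSolution, b: FluxSolution,
                   fold_threshold: float = 2.0,
                   activity_eps: float = 1e-6) -> list:
    """Reactions whose |flux| changes by more than ``fold_threshold`` (x)
    between two solutions, or that switch on/off across ``activity_eps``.

    Ordered by descending fold change; relabeling is symmetric under
    argument swap (increased <-> decreased, switched-on <-> switched-off).
    """
    changes = []
    for rid in sorted(set(a.fluxes) | set(b.fluxes)):
        va, vb = abs(a.fluxes.get(rid, 0.0)), abs(b.fluxes.get(rid, 0.0))
        active_a, active_b = va > activity_eps, vb > activity_eps
        if not active_a and not active_b:
            continue
        if active_a and not active_b:
            changes.append(FluxChange(rid, a.fluxes.get(rid, 0.0),
                                      b.fluxes.get(rid, 0.0),
                                      "switched-off", float("inf")))
        elif active_b and not active_a:
            changes.append(FluxChange(rid, a.fluxes.get(rid, 0.0),
                                      b.fluxes.get(rid, 0.0),
                                      "switched-on", float("inf")))
        else:
            fold = max(va, vb) / min(va, vb)
            if fold > fold_threshold:
                cat = "increased" if vb > va else "decreased"
                changes.append(FluxChange(rid, a.fluxes.get(rid, 0.0),
                                          b.fluxes.get(rid, 0.0), cat, fold))
    changes.sort(key=lambda c: (-c.fold, c.reaction))
    return changes
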