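"""End-to-end orchestration of the hybrid pipeline.

One *condition analysis* runs, in order: value propagation of the fixed
condition, network reduction, minimal trap spaces, projection onto the
mapped metabolic components, zero-flux constraint extraction, FBA, and the
ATP-source / C-flux reports.  :func:`run_pipeline` wraps that in file I/O:
it additionally solves the unconstrained control FBA, compares internal
fluxes between the two conditions, and writes TSV tables plus a JSON
summary into an output directory.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import bridge, fba_analysis, logic_core, metab_io, qual_io
from .bridge import ConstraintSet, MetabolicMapping
from .errors import HybridraError
from .metab_io import MetabolicModel, ObjectiveSpec
from .qual_io import BooleanNetwork, Condition

logger = logging.getLogger("hybridra.pipeline")

__all__ = ["RunConfig", "ConditionResult", "analyze_condition", "run_pipeline"]


@dataclass
class ConditionResult:
    """Everything one condition analysis produced."""

    condition: Condition
    propagated: logic_core.PartialState
    trapspaces: list
    projection: dict
    constraints: ConstraintSet
    solution: fba_analysis.FluxSolution
    atp: fba_analysis.AtpReport | None
    cflux: fba_analysis.CFluxReport | None

    @property
    def summary(self) -> dict:
        s = {
            "condition": self.condition.label,
            "n_fixed_by_propagation": self.propagated.n_fixed,
            "n_fixed_at_0": self.propagated.count(0),
            "n_fixed_at_1": self.propagated.count(1),
            "n_trapspaces": len(self.trapspaces),
            "n_constraints": len(self.constraints),
            "fba_status": self.solution.status,
            "objective_value": self.solution.objective_value,
        }
        if self.atp is not None:
            s["glycolysis_pct"] = self.atp.glycolysis_pct
            s["oxphos_pct"] = self.atp.oxphos_pct
        return s


def analyze_condition(net: BooleanNetwork, condition: Condition,
                      model: MetabolicModel, mapping: MetabolicMapping,
                      objective: ObjectiveSpec, glycolytic_terms, oxphos_terms,
                      parsimonious: bool = False, unclamp: bool = False,
                      trapspace_budget: int = 500_000) -> ConditionResult:
    """Run the full regulatory-to-FBA chain for one condition.

    ``unclamp`` drops the caller's clamped assignments after propagation,
    so that only their propagated consequences constrain the trap-space
    search; by default the clamped components stay fixed throughout.
    """
    condition.resolve(net)
    propagated = logic_core.propagate(net, condition)
    fixed_for_reduction = propagated
    if unclamp:
        kept = {c: v for c, v in propagated.fixed.items()
                if c not in condition.assignments}
        fixed_for_reduction = logic_core.PartialState(kept)
    reduced = logic_core.reduce_network(net, fixed_for_reduction)
    trapspaces = logic_core.minimal_trapspaces(reduced, budget=trapspace_budget)
    projection = bridge.max_projection(trapspaces, mapping)
    constraints = bridge.derive_constraints(projection, mapping, model)
    solution = fba_analysis.solve_fba(model, constraints, objective,
                                      parsimonious=parsimonious)
    atp = cflux = None
    if solution.optimal:
        try:
            atp = fba_analysis.atp_fractions(solution, objective,
                                             glycolytic_terms, oxphos_terms)
        except fba_analysis.UndefinedFractionError:
            logger.warning("objective value is 0 under %r: ATP-source "
                           "fractions left blank", condition.label)
        cflux = fba_analysis.cflux_report(solution, model)
    return ConditionResult(condition, propagated, trapspaces, projection,
                           constraints, solution, atp, cflux)


@dataclass
class RunConfig:
    """Paths and options for a full pipeline run."""

    qual_model: Path
    metabolic_model: Path
    condition: Path
    objective: Path
    exclusions: Path | None = None
    out_dir: Path = Path("hybridra_out")
    parsimonious: bool = False
    unclamp: bool = False
    compartment_suffixes: tuple = metab_io.DEFAULT_COMPARTMENT_SUFFIXES
    reaction_prefixes: tuple = bridge.DEFAULT_REACTION_PREFIXES
    fold_threshold: float = 2.0
    trapspace_budget: int = 500_000

    def validate(self) -> None:
        for name in ("qual_model", "metabolic_model", "condition", "objective"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise HybridraError(f"{name} file does not exist: {p}")
        if self.exclusions is not None and not Path(self.exclusions).exists():
            raise HybridraError(f"exclusions file does not exist: {self.exclusions}")

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {k: (str(v) if isinstance(v, Path) else v) for k, v in d.items()}


def _write_constraints_tsv(constraints: ConstraintSet, path: Path) -> None:
    rows = []
    for rid in sorted(constraints.zeroed):
        for comp, reason in constraints.provenance[rid]:
            rows.append({"reaction": rid, "component": comp, "reason": reason})
    pd.DataFrame(rows, columns=["reaction", "component", "reason"]).to_csv(
        path, sep="\t", index=False)


def _write_cflux_tsv(report: fba_analysis.CFluxReport, path: Path) -> None:
    rows = [{"side": "uptake", "reaction": r, "cflux_pct": p}
            for r, p in sorted(report.uptake.items())]
    rows += [{"side": "secretion", "reaction": r, "cflux_pct": p}
             for r, p in sorted(report.secretion.items())]
    pd.DataFrame(rows, columns=["side", "reaction", "cflux_pct"]).to_csv(
        path, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full pipeline and write all outputs to ``out_dir``.

    The condition run uses the trap-space-derived constraints; the control
    run uses the same model and objective with an empty constraint set.
    Returns the output directory.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(config.as_dict(), indent=2))

    net = qual_io.load_regulatory_model(config.qual_model)
    model = metab_io.load_metabolic_model(
        config.metabolic_model, compartment_suffixes=config.compartment_suffixes)
    condition = qual_io.load_condition(config.condition)
    condition.resolve(net)
    objective, gly, oxp = metab_io.load_objective(config.objective)
    objective.validate(model)
    exclusions = (bridge.load_exclusions(config.exclusions)
                  if config.exclusions else set())
    mapping = bridge.match_components(net, model, exclusions,
                                      reaction_prefixes=config.reaction_prefixes)

    result = analyze_condition(net, condition, model, mapping, objective,
                               gly, oxp, parsimonious=config.parsimonious,
                               unclamp=config.unclamp,
                               trapspace_budget=config.trapspace_budget)
    control_sol = fba_analysis.solve_fba(model, ConstraintSet.empty(), objective,
                                         parsimonious=config.parsimonious)
    control_atp = control_cflux = None
    if control_sol.optimal:
        control_atp = fba_analysis.atp_fractions(control_sol, objective, gly, oxp)
        control_cflux = fba_analysis.cflux_report(control_sol, model)

    # --- tables -----------------------------------------------------
    reduced = logic_core.reduce_network(net, result.propagated)
    logic_core.trapspaces_to_frame(result.trapspaces, reduced).to_csv(
        out / "trapspaces.tsv", sep="\t")
    pd.Series(result.projection, name="max_trapspace_value").rename_axis(
        "component").to_csv(out / "projection.tsv", sep="\t")
    _write_constraints_tsv(result.constraints, out / "constraints.tsv")
    for label, sol in (("condition", result.solution), ("control", control_sol)):
        if sol.optimal:
            pd.Series(sol.fluxes, name="flux").rename_axis("reaction").to_csv(
                out / f"fluxes_{label}.tsv", sep="\t")
    if result.cflux is not None:
        _write_cflux_tsv(result.cflux, out / "cflux_condition.tsv")
    if control_cflux is not None:
        _write_cflux_tsv(control_cflux, out / "cflux_control.tsv")

    changes = []
    if result.solution.optimal and control_sol.optimal:
        internal = set(model.internal_reaction_ids)
        changes = [c for c in fba_analysis.compare_fluxes(
            control_sol, result.solution, config.fold_threshold)
            if c.reaction in internal]
        pd.DataFrame([dataclasses.asdict(c) for c in changes],
                     columns=["reaction", "flux_a", "flux_b", "category", "fold"]
                     ).to_csv(out / "fold_changes.tsv", sep="\t", index=False)

    summary = {
        "condition": result.summary,
        "control": {
            "fba_status": control_sol.status,
            "objective_value": control_sol.objective_value,
            "glycolysis_pct": control_atp.glycolysis_pct if control_atp else None,
            "oxphos_pct": control_atp.oxphos_pct if control_atp else None,
        },
        "n_fold_changes": len(changes),
        "mapping": {
            "n_enzyme_components": len(mapping.enzyme_map),
            "n_metabolite_components": len(mapping.metabolite_map),
            "n_excluded": len(mapping.excluded),
        },
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    logger.info("pipeline finished; outputs in %s", out)
    return out
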