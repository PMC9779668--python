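"""Paired toy regulatory/metabolic systems and random Boolean networks.

This is the package's download-free test surface.  The toy pair is a
miniature of the real use case: a hypoxia-like input drives a master
transcription factor which represses the oxidative branch of a two-branch
ATP-producing metabolic network, so the regulatory state decides whether
the LP optimum is glycolytic or oxidative.  The stoichiometry uses small
integers (2 ATP per glucose via the glycolytic lump, 36 via the oxidative
branch), so every expected optimum is rational and checkable by hand; the
expected-outcome table is computed in closed form here at generation time,
never by the pipeline under test.

Ground truth of the toy pair (uptake cap ``g`` on glucose, ATP yields
``k_g`` < ``k_o`` per glucose):

* regulator ON: the oxidative entry reaction is zero-constrained, the
  optimum is fully glycolytic — objective ``k_g * g``, glycolysis 100%;
* regulator OFF: no constraints; routing all pyruvate oxidatively is
  strictly better, so the optimum is ``(k_g + k_o) * g`` with an OXPHOS
  share of ``k_o / (k_g + k_o)``.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

import cobra

from .bridge import MetabolicMapping, match_components
from .errors import ValidationError
from .expr import And, Const, LogicExpr, Not, Or, Var
from .metab_io import MetabolicModel, ObjectiveSpec, wrap_cobra_model
from .qual_io import BooleanNetwork, Condition, write_regulatory_model

__all__ = ["ToyPair", "make_toy_pair", "random_boolean_network",
           "write_toy_pair", "TOY_EXCLUSIONS"]

#: common metabolic intermediates never treated as mapped metabolites
TOY_EXCLUSIONS = ("glc", "pyr", "lac", "o2", "co2", "atp")

GLUCOSE_CAP = 10.0   # maximal glucose uptake flux
K_GLY = 2            # ATP per glucose, glycolytic lump
K_OX = 36            # ATP per glucose, oxidative branch (2 pyruvate x 18)


@dataclass
class ToyPair:
    """A paired toy system plus its analytically known outcomes.

    ``expected`` maps the regulator input value (0/1) to the closed-form
    outcome dict (trap-space count, constraint count, objective value,
    ATP-source split, dominant C-flux carriers).
    """

    net: BooleanNetwork
    model: MetabolicModel
    mapping: MetabolicMapping
    condition: Condition
    objective: ObjectiveSpec
    glycolytic_terms: frozenset
    oxphos_terms: frozenset
    exclusions: tuple
    expected: dict
    variant: str
    seed: int
    paths: dict = field(default_factory=dict)


def _toy_network() -> BooleanNetwork:
    rules = {
        "HYPOXIA": Var("HYPOXIA"),          # hypoxia-like input
        "GLC": Var("GLC"),                  # glucose availability input
        "HIF1": Var("HYPOXIA"),             # master transcription factor
        "HK": Or((Var("HIF1"), Var("GLC"))),    # glycolytic enzyme
        "LDHA": Var("GLC"),                     # lactate dehydrogenase
        "PDHm": Not(Var("HIF1")),               # oxidative-branch enzyme
        "ACOA": Var("PDHm"),                    # oxidative-branch metabolite
        "NFKB": Not(Var("IKB")),
        "IKB": Not(Var("NFKB")),
        "INFLAM": Var("NFKB"),              # phenotype node, unmapped
    }
    order = ("HYPOXIA", "GLC", "HIF1", "HK", "LDHA", "PDHm", "ACOA",
             "NFKB", "IKB", "INFLAM")
    return BooleanNetwork(order, rules)


def _toy_metabolic_model() -> MetabolicModel:
    m = cobra.Model("toy_metab")

    def met(mid, formula, compartment):
        x = cobra.Metabolite(mid, formula=formula, compartment=compartment)
        m.add_metabolites([x])
        return x

    glc_e = met("glc_e", "C6H12O6", "e")
    glc_c = met("glc_c", "C6H12O6", "c")
    pyr_c = met("pyr_c", "C3H4O3", "c")
    lac_c = met("lac_c", "C3H6O3", "c")
    lac_e = met("lac_e", "C3H6O3", "e")
    acoa_m = met("acoa_m", "C3H4O", "m")
    o2_e = met("o2_e", "O2", "e")
    o2_m = met("o2_m", "O2", "m")
    co2_m = met("co2_m", "CO2", "m")
    co2_e = met("co2_e", "CO2", "e")
    atp_c = met("atp_c", "HO3P", "c")   # carbon-free energy token

    def rxn(rid, stoich, lb, ub):
        r = cobra.Reaction(rid, lower_bound=lb, upper_bound=ub)
        m.add_reactions([r])
        r.add_metabolites(stoich)
        return r

    big = 1000.0
    rxn("EX_glc_e", {glc_e: -1}, -GLUCOSE_CAP, big)
    rxn("R_GLCt", {glc_e: -1, glc_c: 1}, 0, big)
    # glycolytic lump: K_GLY ATP and 2 pyruvate per glucose
    rxn("R_HK", {glc_c: -1, pyr_c: 2, atp_c: K_GLY}, 0, big)
    rxn("R_LDHA", {pyr_c: -1, lac_c: 1}, 0, big)
    rxn("R_LACt", {lac_c: -1, lac_e: 1}, 0, big)
    rxn("EX_lac_e", {lac_e: -1}, 0, big)
    # oxidative branch: entry via PDH, then TCA/OXPHOS lump (K_OX/2 per pyruvate)
    rxn("R_PDHm", {pyr_c: -1, acoa_m: 1}, 0, big)
    rxn("R_TCA", {acoa_m: -1, o2_m: -3, co2_m: 3, atp_c: K_OX // 2}, 0, big)
    rxn("R_O2t", {o2_e: -1, o2_m: 1}, 0, big)
    rxn("EX_o2_e", {o2_e: -1}, -big, big)
    rxn("R_CO2t", {co2_m: -1, co2_e: 1}, 0, big)
    rxn("EX_co2_e", {co2_e: -1}, 0, big)
    rxn("DM_atp_c", {atp_c: -1}, 0, big)
    return wrap_cobra_model(m)


def _expected_table() -> dict:
    """Closed-form LP outcomes of the two-branch network (no pipeline)."""
    g, kg, ko = GLUCOSE_CAP, K_GLY, K_OX
    return {
        1: {  # regulator ON: oxidative entry zeroed -> fully glycolytic
            "n_trapspaces": 2,
            "n_constraints": 1,
            "objective_value": kg * g,
            "glycolysis_pct": 100.0,
            "oxphos_pct": 0.0,
            "uptake_cflux": {"EX_glc_e": 100.0},
            "secretion_cflux": {"EX_lac_e": 100.0},
        },
        0: {  # regulator OFF: oxidative routing strictly dominates
            "n_trapspaces": 2,
            "n_constraints": 0,
            "objective_value": (kg + ko) * g,
            "glycolysis_pct": 100.0 * kg / (kg + ko),
            "oxphos_pct": 100.0 * ko / (kg + ko),
            "uptake_cflux": {"EX_glc_e": 100.0},
            "secretion_cflux": {"EX_co2_e": 100.0},
        },
    }


def make_toy_pair(variant: str = "warburg", seed: int = 0,
                  out_dir=None) -> ToyPair:
    """Build the paired toy system.

    ``variant`` selects the bundled condition over one shared topology:
    ``warburg`` clamps the hypoxia-like input ON, ``control`` clamps it
    OFF (glucose is available in both).  The construction is fully
    deterministic; ``seed`` is recorded for interface parity with
    :func:`random_boolean_network`.  With ``out_dir`` set, the standard
    files (SBML-qual, SBML, condition/objective/exclusion configs and the
    expected-results TSV) are written there as well.
    """
    if variant not in ("warburg", "control"):
        raise ValidationError(f"unknown toy variant {variant!r}")
    net = _toy_network()
    model = _toy_metabolic_model()
    mapping = match_components(net, model, TOY_EXCLUSIONS)
    condition = Condition({"HYPOXIA": 1 if variant == "warburg" else 0, "GLC": 1},
                          label=f"toy-{variant}")
    objective = ObjectiveSpec({"R_HK": float(K_GLY), "R_TCA": float(K_OX // 2)},
                              label="maximal ATP production")
    pair = ToyPair(
        net=net, model=model, mapping=mapping, condition=condition,
        objective=objective,
        glycolytic_terms=frozenset(("R_HK",)),
        oxphos_terms=frozenset(("R_TCA",)),
        exclusions=TOY_EXCLUSIONS,
        expected=_expected_table(),
        variant=variant, seed=seed,
    )
    if out_dir is not None:
        write_toy_pair(pair, out_dir)
    return pair


def write_toy_pair(pair: ToyPair, out_dir) -> dict:
    """Write the toy pair to standard formats and record the paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "qual": out / "toy_regulatory.sbml",
        "metab": out / "toy_metabolic.sbml",
        "condition": out / f"condition_{pair.variant}.yaml",
        "objective": out / "objective.yaml",
        "exclusions": out / "exclusions.txt",
        "expected": out / "expected.tsv",
    }
    write_regulatory_model(pair.net, paths["qual"])
    cobra.io.write_sbml_model(pair.model.cobra_model, str(paths["metab"]))
    cond_lines = "".join(f"{k}: {v}\n" for k, v in pair.condition.assignments.items())
    paths["condition"].write_text(cond_lines)
    paths["objective"].write_text(
        "label: maximal ATP production\n"
        "terms:\n"
        + "".join(f"  {r}: {w}\n" for r, w in sorted(pair.objective.terms.items()))
        + "glycolytic: [" + ", ".join(sorted(pair.glycolytic_terms)) + "]\n"
        + "oxphos: [" + ", ".join(sorted(pair.oxphos_terms)) + "]\n")
    paths["exclusions"].write_text("".join(f"{n}\n" for n in pair.exclusions))
    rows = ["regulator\tn_trapspaces\tn_constraints\tobjective_value"
            "\tglycolysis_pct\toxphos_pct"]
    for v in (0, 1):
        e = pair.expected[v]
        rows.append(f"{v}\t{e['n_trapspaces']}\t{e['n_constraints']}"
                    f"\t{e['objective_value']}\t{e['glycolysis_pct']:.6f}"
                    f"\t{e['oxphos_pct']:.6f}")
    paths["expected"].write_text("\n".join(rows) + "\n")
    pair.paths = {k: str(v) for k, v in paths.items()}
    return pair.paths


# ---------------------------------------------------------------------------
# random networks for property tests
# ---------------------------------------------------------------------------

def random_boolean_network(n: int, k: int = 3, seed: int = 0,
                           p_input: float = 0.15,
                           p_const: float = 0.05) -> BooleanNetwork:
    """A reproducible random Boolean network: ``n`` components, random
    AND/OR/NOT rule trees over at most ``k`` regulators each."""
    if n < 1 or k < 1:
        raise ValidationError("need n >= 1 and k >= 1")
    rng = random.Random(seed)
    comps = tuple(f"n{i}" for i in range(n))

    def rand_tree(vars_: list) -> LogicExpr:
        if len(vars_) == 1:
            leaf: LogicExpr = Var(vars_[0])
            return Not(leaf) if rng.random() < 0.5 else leaf
        cut = rng.randint(1, len(vars_) - 1)
        left, right = rand_tree(vars_[:cut]), rand_tree(vars_[cut:])
        op = And if rng.random() < 0.5 else Or
        e: LogicExpr = op((left, right))
        return Not(e) if rng.random() < 0.25 else e

    rules = {}
    for c in comps:
        u = rng.random()
        if u < p_const:
            rules[c] = Const(rng.randint(0, 1))
        elif u < p_const + p_input:
            rules[c] = Var(c)
        else:
            indeg = rng.randint(1, min(k, n))
            regs = rng.sample(comps, indeg)
            rules[c] = rand_tree(list(regs))
    return BooleanNetwork(comps, rules)
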