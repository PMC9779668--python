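"""Constraint-based metabolic model I/O and boundary accounting.

The SBML (Level 3 + FBC) file is read with cobrapy; this module wraps the
cobra model with the extra bookkeeping the hybrid pipeline needs:

* a *base identifier* per metabolite — the BiGG-style ID with its trailing
  compartment suffix stripped — used to match compartment-blind regulatory
  component names against metabolites;
* an explicit carbon count per metabolite, parsed from the elemental
  formula (metabolites without a parseable formula are flagged
  carbon-unknown and C-flux computations refuse them rather than guess);
* a single internal exchange convention: every boundary reaction is
  normalized so that *positive* flux exports the metabolite and *negative*
  flux imports it, whatever the source dialect wrote.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import cobra
from cobra.io import read_sbml_model, write_sbml_model

from .errors import FormulaError, ValidationError

logger = logging.getLogger("hybridra.metab_io")

__all__ = [
    "MetabolicModel", "ObjectiveSpec",
    "load_metabolic_model", "save_metabolic_model",
    "carbon_count", "classify_boundary",
    "DEFAULT_COMPARTMENT_SUFFIXES",
]

#: trailing compartment tags stripped when computing metabolite base IDs
DEFAULT_COMPARTMENT_SUFFIXES = ("_c", "_m", "_e", "_i", "_x")

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def carbon_count(formula: str) -> int:
    """Number of carbon atoms in a Hill-notation elemental formula.

    ``"C6H12O6" -> 6``, ``"H2O" -> 0``.  An empty or unparseable formula
    raises :class:`FormulaError` — never a silent 0.
    """
    if not formula or not isinstance(formula, str):
        raise FormulaError(f"missing or non-string formula: {formula!r}")
    pos, carbons = 0, 0
    while pos < len(formula):
        m = _FORMULA_TOKEN.match(formula, pos)
        if not m:
            raise FormulaError(f"unparseable formula {formula!r} at {formula[pos:]!r}")
        element, count = m.group(1), int(m.group(2) or 1)
        if element == "C":
            carbons += count
        pos = m.end()
    return carbons


def strip_compartment(met_id: str, suffixes=DEFAULT_COMPARTMENT_SUFFIXES) -> str:
    for s in suffixes:
        if met_id.endswith(s):
            return met_id[: -len(s)]
    return met_id


@dataclass
class MetaboliteInfo:
    formula: str | None
    compartment: str
    base_id: str
    carbons: int | None  # None = carbon-unknown


@dataclass
class MetabolicModel:
    """A constraint-based metabolic model plus hybrid-pipeline metadata.

    ``cobra_model`` holds stoichiometry, bounds and the boundary set;
    ``metabolites`` carries formula/compartment/base-ID information;
    ``exchange_sign`` maps each boundary reaction to +1 or -1 so that
    ``sign * flux`` is always in the export-positive convention.
    """

    cobra_model: cobra.Model
    metabolites: dict = field(default_factory=dict)
    compartment_suffixes: tuple = DEFAULT_COMPARTMENT_SUFFIXES
    exchange_sign: dict = field(default_factory=dict)

    @property
    def reactions(self):
        return self.cobra_model.reactions

    @property
    def boundary(self) -> frozenset:
        return frozenset(r.id for r in self.cobra_model.boundary)

    @property
    def internal_reaction_ids(self) -> list:
        b = self.boundary
        return [r.id for r in self.cobra_model.reactions if r.id not in b]

    def reaction(self, rid: str) -> cobra.Reaction:
        return self.cobra_model.reactions.get_by_id(rid)

    def has_reaction(self, rid: str) -> bool:
        return rid in self.cobra_model.reactions

    def boundary_metabolite(self, rid: str) -> str:
        """The single metabolite a boundary reaction exchanges."""
        rxn = self.reaction(rid)
        mets = [m.id for m in rxn.metabolites]
        if len(mets) != 1:
            raise ValidationError(
                f"boundary reaction {rid!r} exchanges {len(mets)} metabolites")
        return mets[0]

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(self.cobra_model.copy(), dict(self.metabolites),
                              self.compartment_suffixes, dict(self.exchange_sign))

    def __repr__(self):
        nb = len(self.boundary)
        return (f"MetabolicModel({len(self.metabolites)} metabolites, "
                f"{len(self.cobra_model.reactions) - nb} internal reactions, "
                f"{nb} boundary reactions)")


@dataclass(frozen=True)
class ObjectiveSpec:
    """A weighted sum of reaction fluxes to maximize, e.g. the sum of the
    cell's ATP-producing reactions."""

    terms: dict
    label: str = "objective"

    def __post_init__(self):
        if not self.terms:
            raise ValidationError("objective must name at least one reaction")

    def validate(self, model: MetabolicModel) -> None:
        missing = [r for r in self.terms if not model.has_reaction(r)]
        if missing:
            raise ValidationError(
                f"objective reaction(s) absent from model: {sorted(missing)}")

    @classmethod
    def from_mapping(cls, data: Mapping, label: str = "objective") -> "ObjectiveSpec":
        terms = {str(k): float(v) for k, v in data.items()}
        return cls(terms, label)


def load_objective(path) -> tuple:
    """Read an objective YAML file.

    Expected layout::

        label: maximal ATP production
        terms: {R_PGK: 1, R_PYK: 1, R_ATPS: 1}
        glycolytic: [R_PGK, R_PYK]
        oxphos: [R_ATPS]

    Returns ``(ObjectiveSpec, glycolytic_terms, oxphos_terms)``; the two
    groups must partition the objective terms.
    """
    import yaml

    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict) or "terms" not in data:
        raise ValidationError(f"{path} must define a 'terms' mapping")
    spec = ObjectiveSpec.from_mapping(data["terms"],
                                      label=str(data.get("label", "objective")))
    gly = set(data.get("glycolytic", ()))
    oxp = set(data.get("oxphos", ()))
    if gly | oxp != set(spec.terms) or gly & oxp:
        raise ValidationError(
            "glycolytic and oxphos groups must partition the objective terms")
    return spec, gly, oxp


def load_metabolic_model(path, compartment_suffixes=DEFAULT_COMPARTMENT_SUFFIXES,
                         ) -> MetabolicModel:
    """Read an SBML/FBC file into a :class:`MetabolicModel`.

    Validates bound ordering (lb <= ub for every reaction), computes
    compartment-stripped base IDs and carbon counts, and records the sign
    normalization that maps every boundary reaction onto the
    export-positive exchange convention.
    """
    path = Path(path)
    _check_fbc_bounds(path)
    try:
        model = read_sbml_model(str(path))
    except ValueError as e:  # e.g. solver-level bound rejection
        raise ValidationError(f"invalid flux bounds in {path}: {e}") from e
    return wrap_cobra_model(model, compartment_suffixes)


def _check_fbc_bounds(path) -> None:
    """Pre-scan FBC bound parameters so a bound-ordering violation is
    reported with the reaction's name instead of a solver error."""
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    model = doc.getModel()
    if model is None:
        return  # let cobra produce its own parse error
    params = {p.getId(): p.getValue() for p in model.getListOfParameters()}
    for rxn in model.getListOfReactions():
        fbc = rxn.getPlugin("fbc")
        if fbc is None:
            continue
        lb = params.get(fbc.getLowerFluxBound()) if fbc.isSetLowerFluxBound() else None
        ub = params.get(fbc.getUpperFluxBound()) if fbc.isSetUpperFluxBound() else None
        if lb is not None and ub is not None and lb > ub:
            raise ValidationError(
                f"reaction {rxn.getId()!r} has lb={lb} > ub={ub}")


def wrap_cobra_model(model: cobra.Model,
                     compartment_suffixes=DEFAULT_COMPARTMENT_SUFFIXES,
                     ) -> MetabolicModel:
    for rxn in model.reactions:
        if rxn.lower_bound > rxn.upper_bound:
            raise ValidationError(
                f"reaction {rxn.id!r} has lb={rxn.lower_bound} > ub={rxn.upper_bound}")

    mets = {}
    for met in model.metabolites:
        formula = met.formula if met.formula else None
        try:
            carbons = carbon_count(formula) if formula is not None else None
        except FormulaError:
            carbons = None
        mets[met.id] = MetaboliteInfo(
            formula=formula,
            compartment=met.compartment or "",
            base_id=strip_compartment(met.id, compartment_suffixes),
            carbons=carbons,
        )

    sign = {}
    for rxn in model.boundary:
        coeffs = list(rxn.metabolites.values())
        if len(coeffs) != 1:
            raise ValidationError(
                f"boundary reaction {rxn.id!r} must exchange exactly one metabolite")
        # stoich -1 (met ->) is already export-positive; stoich +1 (-> met)
        # needs its flux sign flipped to match.
        sign[rxn.id] = -1 if coeffs[0] > 0 else 1

    wrapped = MetabolicModel(model, mets, tuple(compartment_suffixes), sign)
    logger.info("loaded metabolic model %s: %d metabolites, %d reactions "
                "(%d boundary)", model.id or "<unnamed>", len(mets),
                len(model.reactions), len(wrapped.boundary))
    return wrapped


def save_metabolic_model(model: MetabolicModel, path) -> None:
    write_sbml_model(model.cobra_model, str(path))


def classify_boundary(model: MetabolicModel, solution,
                      zero_tol: float = 1e-9) -> tuple:
    """Partition boundary reactions by flux direction.

    Returns ``(uptake, secretion)`` sets of reaction IDs under the
    normalized exchange convention: negative normalized flux imports the
    metabolite (uptake), positive exports it (secretion).  Boundary
    reactions with |flux| <= ``zero_tol`` appear in neither set.
    """
    fluxes = solution.fluxes if hasattr(solution, "fluxes") else solution
    uptake, secretion = set(), set()
    for rid in model.boundary:
        v = fluxes[rid] * model.exchange_sign.get(rid, 1)
        if v < -zero_tol:
            uptake.add(rid)
        elif v > zero_tol:
            secretion.add(rid)
    return uptake, secretion
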