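"""Regulatory-to-metabolic bridging.

The regulatory model cannot tell a signaling protein from a metabolic
enzyme, nor a second messenger from a metabolite; the bridge identifies
the regulatory components that *are* metabolic — by BiGG-style name
matching against the metabolic model — projects trap spaces onto them, and
turns components that are provably OFF in every minimal trap space into
zero-flux constraints:

* an enzyme component at 0 zeroes the reactions it catalyzes (matched by
  reaction ID);
* a metabolite component at 0 zeroes every reaction able to produce any of
  its compartment instances.

Components whose maximal trap-space value is 1 (or FREE, which means
"sometimes active") contribute nothing: qualitative activity says nothing
about flux magnitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .errors import AmbiguousMappingError, IntegrityError, ValidationError
from .logic_core import FREE, TrapSpace
from .metab_io import MetabolicModel
from .qual_io import BooleanNetwork

logger = logging.getLogger("hybridra.bridge")

__all__ = [
    "MetabolicMapping", "ConstraintSet",
    "match_components", "max_projection",
    "producing_reactions", "derive_constraints",
    "load_exclusions", "DEFAULT_REACTION_PREFIXES",
]

#: prefixes stripped from reaction IDs before name comparison
DEFAULT_REACTION_PREFIXES = ("R_",)

ENZYME_CATALYZED = "enzyme-catalyzed"
METABOLITE_PRODUCING = "metabolite-producing"


@dataclass
class MetabolicMapping:
    """Which regulatory components are metabolic, and what they map to.

    A component appears in at most one of ``enzyme_map`` /
    ``metabolite_map`` / ``excluded``.
    """

    enzyme_map: dict = field(default_factory=dict)      # comp -> set of reaction IDs
    metabolite_map: dict = field(default_factory=dict)  # comp -> set of metabolite IDs
    excluded: set = field(default_factory=set)

    @property
    def mapped_components(self) -> list:
        return sorted(set(self.enzyme_map) | set(self.metabolite_map))

    def __repr__(self):
        return (f"MetabolicMapping({len(self.enzyme_map)} enzymes, "
                f"{len(self.metabolite_map)} metabolites, "
                f"{len(self.excluded)} excluded)")


@dataclass
class ConstraintSet:
    """Reactions forced to zero flux, with per-reaction provenance.

    ``provenance[rid]`` lists ``(component, reason)`` pairs; a reaction
    constrained both through the enzyme catalyzing it and through a
    metabolite it produces carries two entries (a dually extracted
    constraint).
    """

    zeroed: set = field(default_factory=set)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if set(self.provenance) != set(self.zeroed):
            raise ValidationError("provenance must cover exactly the zeroed set")

    def __len__(self):
        return len(self.zeroed)

    @classmethod
    def empty(cls) -> "ConstraintSet":
        return cls(set(), {})


def load_exclusions(path) -> set:
    """Read a one-name-per-line exclusion list (common metabolic
    intermediates that should not be treated as mapped metabolites)."""
    names = set()
    for line in open(path):
        line = line.strip()
        if line and not line.startswith("#"):
            names.add(line)
    return names


def _normalize(name: str, prefixes, suffixes) -> str:
    for p in prefixes:
        if name.startswith(p):
            name = name[len(p):]
            break
    for s in suffixes:
        if name.endswith(s):
            name = name[: -len(s)]
            break
    return name.casefold()


def match_components(net: BooleanNetwork, model: MetabolicModel,
                     exclusions=(), reaction_prefixes=DEFAULT_REACTION_PREFIXES,
                     ) -> MetabolicMapping:
    """Match regulatory component names against the metabolic model.

    Normalization is case-fold plus stripping the configured reaction
    prefixes and the model's compartment suffixes.  The exclusion list is
    applied before metabolite matching.  A component matching both a
    metabolite and a reaction is an error — no silent priority.
    """
    suffixes = model.compartment_suffixes
    excl_norm = {_normalize(e, reaction_prefixes, suffixes) for e in exclusions}

    met_lookup = {}
    for mid, info in model.metabolites.items():
        met_lookup.setdefault(info.base_id.casefold(), set()).add(mid)
    rxn_lookup = {}
    for rxn in model.cobra_model.reactions:
        rxn_lookup.setdefault(_normalize(rxn.id, reaction_prefixes, ()), set()).add(rxn.id)

    mapping = MetabolicMapping()
    for comp in net.components:
        norm = _normalize(comp, reaction_prefixes, suffixes)
        if norm in excl_norm:
            mapping.excluded.add(comp)
            continue
        in_mets = norm in met_lookup
        in_rxns = norm in rxn_lookup
        if in_mets and in_rxns:
            raise AmbiguousMappingError(
                f"component {comp!r} matches both metabolite(s) "
                f"{sorted(met_lookup[norm])} and reaction(s) "
                f"{sorted(rxn_lookup[norm])}")
        if in_rxns:
            mapping.enzyme_map[comp] = set(rxn_lookup[norm])
        elif in_mets:
            mapping.metabolite_map[comp] = set(met_lookup[norm])
    logger.info("matched %d enzyme and %d metabolite components (%d excluded)",
                len(mapping.enzyme_map), len(mapping.metabolite_map),
                len(mapping.excluded))
    return mapping


def max_projection(trapspaces: list, mapping: MetabolicMapping) -> dict:
    """Maximal trap-space value of every mapped component.

    0 iff the component is fixed at 0 in *every* trap space; 1 otherwise.
    A FREE value counts as potentially active (1).  A component absent
    from every trap space's domain is treated as FREE with a warning.
    """
    if not trapspaces:
        raise ValidationError("trap-space list is empty")
    projection = {}
    for comp in mapping.mapped_components:
        values = []
        for ts in trapspaces:
            v = ts.get(comp) if isinstance(ts, TrapSpace) else ts.get(comp)
            values.append(v)
        if all(v is FREE for v in values):
            logger.warning("component %r absent from all trap-space domains; "
                           "treated as potentially active", comp)
            projection[comp] = 1
        else:
            projection[comp] = 0 if all(v == 0 for v in values) else 1
    return projection


def producing_reactions(model: MetabolicModel, met_id: str) -> set:
    """Reactions that can produce ``met_id`` in some feasible direction:
    positive stoichiometry with ub > 0, or negative stoichiometry with
    lb < 0 (reverse direction).  Boundary reactions are included."""
    if met_id not in model.metabolites:
        raise ValidationError(f"unknown metabolite {met_id!r}")
    met = model.cobra_model.metabolites.get_by_id(met_id)
    out = set()
    for rxn in met.reactions:
        coeff = rxn.metabolites[met]
        if (coeff > 0 and rxn.upper_bound > 0) or (coeff < 0 and rxn.lower_bound < 0):
            out.add(rxn.id)
    return out


def derive_constraints(projection: dict, mapping: MetabolicMapping,
                       model: MetabolicModel) -> ConstraintSet:
    """Zero-flux constraints from components whose maximal trap-space value
    is 0: catalyzed reactions for enzymes, producing reactions (over all
    compartment instances) for metabolites.  Components at 1 contribute
    nothing."""
    zeroed, provenance = set(), {}

    def add(rid, comp, reason):
        if not model.has_reaction(rid):
            raise IntegrityError(
                f"constraint for {comp!r} names unknown reaction {rid!r}")
        zeroed.add(rid)
        provenance.setdefault(rid, []).append((comp, reason))

    for comp, rids in sorted(mapping.enzyme_map.items()):
        if projection.get(comp, 1) == 0:
            for rid in sorted(rids):
                add(rid, comp, ENZYME_CATALYZED)
    for comp, mids in sorted(mapping.metabolite_map.items()):
        if projection.get(comp, 1) == 0:
            for mid in sorted(mids):
                for rid in sorted(producing_reactions(model, mid)):
                    add(rid, comp, METABOLITE_PRODUCING)

    logger.info("derived %d zero-flux constraints", len(zeroed))
    return ConstraintSet(zeroed, provenance)
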