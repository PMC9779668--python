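"""Component matching, trap-space projection and constraint extraction."""

import cobra
import pytest

from hybridra import (PartialState, TrapSpace, derive_constraints,
                      match_components, max_projection, producing_reactions)
from hybridra.bridge import (ENZYME_CATALYZED, METABOLITE_PRODUCING,
                             ConstraintSet, MetabolicMapping)
from hybridra.errors import (AmbiguousMappingError, IntegrityError,
                             ValidationError)
from hybridra.expr import Var
from hybridra.metab_io import wrap_cobra_model
from hybridra.qual_io import BooleanNetwork


def ts(**fixed):
    return TrapSpace(PartialState(fixed), minimal=True)


# --- matching ----------------------------------------------------------

def test_toy_matching(toy_warburg):
    m = toy_warburg.mapping
    assert m.enzyme_map == {"HK": {"R_HK"}, "LDHA": {"R_LDHA"},
                            "PDHm": {"R_PDHm"}}
    assert m.metabolite_map == {"ACOA": {"acoa_m"}}
    assert m.excluded == {"GLC"}


def test_enzyme_matching_strips_reaction_prefix(toy_warburg):
    # "PDHm" matches reaction "R_PDHm" after stripping the R_ prefix
    assert "PDHm" in toy_warburg.mapping.enzyme_map


def test_exclusion_precedence(toy_warburg):
    # GLC would match metabolite glc_e/glc_c but is excluded first
    assert "GLC" not in toy_warburg.mapping.metabolite_map


def test_ambiguous_name_aborts():
    m = cobra.Model("amb")
    met = cobra.Metabolite("akg_c", formula="C5H4O5", compartment="c")
    r = cobra.Reaction("R_AKG", lower_bound=0, upper_bound=1)
    m.add_reactions([r])
    r.add_metabolites({met: -1})
    wrapped = wrap_cobra_model(m)
    net = BooleanNetwork(("AKG",), {"AKG": Var("AKG")})
    with pytest.raises(AmbiguousMappingError, match="AKG"):
        match_components(net, wrapped)


# --- projection --------------------------------------------------------

def test_max_projection_semantics(caplog):
    mapping = MetabolicMapping(enzyme_map={"E": {"R_E"}},
                               metabolite_map={"M": {"m_c"}})
    # E fixed 0 everywhere -> 0 ; M is 0 in two spaces but 1 in one -> 1
    spaces = [ts(E=0, M=0), ts(E=0, M=0), ts(E=0, M=1)]
    proj = max_projection(spaces, mapping)
    assert proj == {"E": 0, "M": 1}
    # FREE counts as potentially active
    spaces = [ts(E=0), ts(E=0, M=0)]
    assert max_projection(spaces, mapping)["M"] == 1
    # component absent everywhere -> warned, treated as 1
    import logging
    with caplog.at_level(logging.WARNING, logger="hybridra.bridge"):
        proj = max_projection([ts(E=0)], mapping)
    assert proj["M"] == 1
    assert any("M" in rec.message for rec in caplog.records)


def test_max_projection_requires_trapspaces():
    with pytest.raises(ValidationError):
        max_projection([], MetabolicMapping())


# --- producing reactions ----------------------------------------------

def _two_met_model(lb, ub):
    m = cobra.Model("p")
    a = cobra.Metabolite("a_c", formula="C", compartment="c")
    b = cobra.Metabolite("b_c", formula="C", compartment="c")
    r = cobra.Reaction("R_AB", lower_bound=lb, upper_bound=ub)
    m.add_reactions([r])
    r.add_metabolites({a: -1, b: 1})
    return wrap_cobra_model(m)


def test_producing_reactions_direction_rules():
    irreversible = _two_met_model(0, 10)      # a -> b only
    assert producing_reactions(irreversible, "b_c") == {"R_AB"}
    assert producing_reactions(irreversible, "a_c") == set()
    reversible = _two_met_model(-10, 10)      # a <-> b
    assert producing_reactions(reversible, "a_c") == {"R_AB"}


def test_producing_reactions_toy(toy_warburg):
    assert producing_reactions(toy_warburg.model, "acoa_m") == {"R_PDHm"}
    # boundary reactions are included when they can produce (import)
    assert "EX_glc_e" in producing_reactions(toy_warburg.model, "glc_e")


# --- constraint extraction ---------------------------------------------

def test_dual_provenance(toy_warburg):
    """An enzyme at 0 whose product metabolite is also at 0 constrains the
    shared reaction in two distinct ways."""
    proj = {"HK": 1, "LDHA": 1, "PDHm": 0, "ACOA": 0}
    cs = derive_constraints(proj, toy_warburg.mapping, toy_warburg.model)
    assert cs.zeroed == {"R_PDHm"}
    reasons = {r for _, r in cs.provenance["R_PDHm"]}
    assert reasons == {ENZYME_CATALYZED, METABOLITE_PRODUCING}


def test_all_active_yields_empty_set(toy_warburg):
    proj = {c: 1 for c in toy_warburg.mapping.mapped_components}
    cs = derive_constraints(proj, toy_warburg.mapping, toy_warburg.model)
    assert len(cs) == 0


def test_constraint_soundness_and_monotonicity(toy_warburg):
    mapping, model = toy_warburg.mapping, toy_warburg.model
    small = {"HK": 1, "LDHA": 1, "PDHm": 0, "ACOA": 1}
    large = {"HK": 1, "LDHA": 0, "PDHm": 0, "ACOA": 0}
    cs_small = derive_constraints(small, mapping, model)
    cs_large = derive_constraints(large, mapping, model)
    # soundness: every provenance component projects to 0
    for rid in cs_large.zeroed:
        for comp, _ in cs_large.provenance[rid]:
            assert large[comp] == 0
    # monotonicity: more zeros never shrink the zeroed set
    assert cs_small.zeroed <= cs_large.zeroed


def test_unknown_reaction_in_constraints(toy_warburg):
    mapping = MetabolicMapping(enzyme_map={"X": {"R_NOPE"}})
    with pytest.raises(IntegrityError):
        derive_constraints({"X": 0}, mapping, toy_warburg.model)


def test_provenance_must_cover_zeroed():
    with pytest.raises(ValidationError):
        ConstraintSet({"R_A"}, {})
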