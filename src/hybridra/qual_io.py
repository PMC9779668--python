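"""SBML-qual I/O: logical regulatory models and condition files.

Models are read with libsbml's ``qual`` extension into an immutable
:class:`BooleanNetwork`: an ordered set of components, one Boolean update
rule per component, and a structurally detected set of inputs.  Only
strictly Boolean models are accepted (every qualitative species with
maximum level 1); multi-valued models are refused up front.

Conditions — fixed 0/1 assignments for a set of components, e.g. a
cell-type-specific configuration of ligand inputs — are flat ``name: value``
YAML mappings.
"""

from __future__ import annotations

import difflib
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import libsbml
import yaml

from .errors import (
    ContradictionError,
    ParseError,
    ResolutionError,
    UnsupportedFormalismError,
    ValidationError,
)
from .expr import And, Const, FALSE, LogicExpr, Not, Or, TRUE, Var

logger = logging.getLogger("hybridra.qual_io")

__all__ = [
    "BooleanNetwork", "Condition",
    "load_regulatory_model", "write_regulatory_model", "load_condition",
]

_SID = re.compile(r"^[A-Za-z_][A-Za-z0-9_]*$")


@dataclass(frozen=True)
class BooleanNetwork:
    """A Boolean regulatory network.

    Parameters
    ----------
    components : tuple of str
        Ordered, unique component IDs (SBML-qual species IDs verbatim).
    rules : dict
        ``component -> LogicExpr``; every component has exactly one rule.
        A component loaded without a transition gets the identity rule on
        itself.
    names : dict
        Optional human-readable ``name`` attributes, metadata only.
    """

    components: tuple
    rules: dict
    names: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.components)) != len(self.components):
            dupes = sorted({c for c in self.components
                            if list(self.components).count(c) > 1})
            raise ValidationError(f"duplicate component IDs: {dupes}")
        declared = set(self.components)
        if set(self.rules) != declared:
            raise ValidationError("rules and components do not cover the same IDs")
        for c, rule in self.rules.items():
            undeclared = rule.support() - declared
            if undeclared:
                raise ValidationError(
                    f"rule of {c!r} references undeclared species: {sorted(undeclared)}")

    @property
    def inputs(self) -> frozenset:
        """Components with no upstream regulators: the rule is either the
        identity on the component itself or references no variable at all."""
        return frozenset(
            c for c in self.components
            if self.rules[c] == Var(c) or not self.rules[c].support()
        )

    @property
    def n_interactions(self) -> int:
        """Total number of regulator->target arcs (identity self-arcs of
        inputs excluded)."""
        return sum(len(self.rules[c].support())
                   for c in self.components if c not in self.inputs)

    def replace_rules(self, new_rules: Mapping[str, LogicExpr]) -> "BooleanNetwork":
        rules = dict(self.rules)
        rules.update(new_rules)
        return BooleanNetwork(self.components, rules, self.names)

    def __repr__(self):
        return (f"BooleanNetwork({len(self.components)} components, "
                f"{len(self.inputs)} inputs, {self.n_interactions} interactions)")


@dataclass(frozen=True)
class Condition:
    """A set of fixed binary assignments, e.g. disease-specific initial
    conditions for ligand inputs and clamped intermediates."""

    assignments: dict
    label: str = ""

    def __post_init__(self):
        for k, v in self.assignments.items():
            if v not in (0, 1):
                raise ValidationError(
                    f"condition value for {k!r} must be 0 or 1, got {v!r}")

    def resolve(self, net: BooleanNetwork) -> None:
        """Validate every assigned name against ``net``; raises
        :class:`ResolutionError` listing near-matches before any analysis."""
        declared = set(net.components)
        unknown = [k for k in self.assignments if k not in declared]
        if unknown:
            hints = {k: difflib.get_close_matches(k, net.components, n=3)
                     for k in unknown}
            msg = "; ".join(f"{k!r} (near: {', '.join(v) or 'none'})"
                            for k, v in hints.items())
            raise ResolutionError(f"unknown component name(s): {msg}",
                                  near_matches=sum(hints.values(), []))

    def merge(self, other: "Condition") -> "Condition":
        """Union of assignments; a component fixed to both 0 and 1 is an
        error."""
        merged = dict(self.assignments)
        for k, v in other.assignments.items():
            if merged.get(k, v) != v:
                raise ContradictionError(
                    f"component {k!r} fixed to both {merged[k]} and {v}")
            merged[k] = v
        label = " + ".join(s for s in (self.label, other.label) if s)
        return Condition(merged, label)

    def flip(self, component: str) -> "Condition":
        """Copy with one component's value flipped (knock-out / knock-in)."""
        if component not in self.assignments:
            raise ValidationError(f"{component!r} not in condition")
        new = dict(self.assignments)
        new[component] = 1 - new[component]
        return Condition(new, f"{self.label}:{component}->{new[component]}")


# ---------------------------------------------------------------------------
# MathML <-> LogicExpr
# ---------------------------------------------------------------------------

def _ast_to_expr(node: libsbml.ASTNode) -> LogicExpr:
    t = node.getType()
    if t == libsbml.AST_LOGICAL_AND:
        kids = [_ast_to_expr(node.getChild(i)) for i in range(node.getNumChildren())]
        return And(tuple(kids)).simplified() if kids else TRUE
    if t == libsbml.AST_LOGICAL_OR:
        kids = [_ast_to_expr(node.getChild(i)) for i in range(node.getNumChildren())]
        return Or(tuple(kids)).simplified() if kids else FALSE
    if t == libsbml.AST_LOGICAL_NOT:
        return Not(_ast_to_expr(node.getChild(0))).simplified()
    if t == libsbml.AST_LOGICAL_XOR:
        kids = [_ast_to_expr(node.getChild(i)) for i in range(node.getNumChildren())]
        e = kids[0]
        for k in kids[1:]:
            e = Or((And((e, Not(k))), And((Not(e), k)))).simplified()
        return e
    if t == libsbml.AST_CONSTANT_TRUE:
        return TRUE
    if t == libsbml.AST_CONSTANT_FALSE:
        return FALSE
    if t == libsbml.AST_INTEGER:
        v = node.getInteger()
        if v in (0, 1):
            return Const(v)
        raise UnsupportedFormalismError(f"integer constant {v} in Boolean rule")
    if t == libsbml.AST_NAME:
        return Var(node.getName())
    if t in (libsbml.AST_RELATIONAL_EQ, libsbml.AST_RELATIONAL_NEQ,
             libsbml.AST_RELATIONAL_GEQ, libsbml.AST_RELATIONAL_GT,
             libsbml.AST_RELATIONAL_LEQ, libsbml.AST_RELATIONAL_LT):
        return _relational_to_expr(node, t)
    raise ParseError(f"unsupported MathML construct: {node.getName() or t}")


def _relational_to_expr(node, t) -> LogicExpr:
    """Comparisons of a Boolean species against an integer threshold, the
    idiom CaSQ/GINsim emit (e.g. ``geq(X, 1)``)."""
    if node.getNumChildren() != 2:
        raise ParseError("relational operator must be binary")
    a, b = node.getChild(0), node.getChild(1)
    # normalize to (variable OP constant)
    flip = {libsbml.AST_RELATIONAL_GEQ: libsbml.AST_RELATIONAL_LEQ,
            libsbml.AST_RELATIONAL_GT: libsbml.AST_RELATIONAL_LT,
            libsbml.AST_RELATIONAL_LEQ: libsbml.AST_RELATIONAL_GEQ,
            libsbml.AST_RELATIONAL_LT: libsbml.AST_RELATIONAL_GT}
    if a.getType() == libsbml.AST_INTEGER and b.getType() == libsbml.AST_NAME:
        a, b = b, a
        t = flip.get(t, t)
    if a.getType() != libsbml.AST_NAME or b.getType() != libsbml.AST_INTEGER:
        raise ParseError("relational term must compare a species to an integer")
    var, n = Var(a.getName()), b.getInteger()
    if t == libsbml.AST_RELATIONAL_EQ:
        if n == 0:
            return Not(var)
        if n == 1:
            return var
        return FALSE
    if t == libsbml.AST_RELATIONAL_NEQ:
        if n == 0:
            return var
        if n == 1:
            return Not(var)
        return TRUE
    if t == libsbml.AST_RELATIONAL_GEQ:
        return TRUE if n <= 0 else (var if n == 1 else FALSE)
    if t == libsbml.AST_RELATIONAL_GT:
        return var if n == 0 else FALSE if n >= 1 else TRUE
    if t == libsbml.AST_RELATIONAL_LEQ:
        return TRUE if n >= 1 else Not(var)
    if t == libsbml.AST_RELATIONAL_LT:
        return FALSE if n <= 0 else (Not(var) if n == 1 else TRUE)
    raise ParseError("unreachable relational type")  # pragma: no cover


def _expr_to_l3(e: LogicExpr) -> str:
    if isinstance(e, Const):
        return "true" if e.value else "false"
    if isinstance(e, Var):
        if not _SID.match(e.name):
            raise ValidationError(f"{e.name!r} is not a valid SBML identifier")
        return e.name
    if isinstance(e, Not):
        return f"!({_expr_to_l3(e.arg)})"
    if isinstance(e, And):
        return "(" + " && ".join(_expr_to_l3(a) for a in e.args) + ")"
    if isinstance(e, Or):
        return "(" + " || ".join(_expr_to_l3(a) for a in e.args) + ")"
    raise TypeError(type(e))


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _check_sbml_errors(doc: libsbml.SBMLDocument, path) -> None:
    fatal = []
    for i in range(doc.getNumErrors()):
        err = doc.getError(i)
        if err.getSeverity() >= libsbml.LIBSBML_SEV_ERROR:
            fatal.append(f"line {err.getLine()}: {err.getMessage().strip()}")
    if fatal:
        raise ParseError(f"cannot parse {path}: " + " | ".join(fatal))


def load_regulatory_model(path) -> BooleanNetwork:
    """Read an SBML-qual file into a :class:`BooleanNetwork`.

    Each transition's function terms are compiled into a single canonical
    rule per output component (first-matching-term semantics folded into
    one expression; unreachable default branches disappear in the fold).
    Species without a transition keep the identity rule and are therefore
    inputs.
    """
    path = Path(path)
    doc = libsbml.readSBMLFromFile(str(path))
    _check_sbml_errors(doc, path)
    model = doc.getModel()
    if model is None:
        raise ParseError(f"{path} contains no SBML model")
    qual = model.getPlugin("qual")
    if qual is None or qual.getNumQualitativeSpecies() == 0:
        raise ValidationError(f"{path} is not an SBML-qual model (no qualitative species)")

    components, names = [], {}
    for i in range(qual.getNumQualitativeSpecies()):
        qs = qual.getQualitativeSpecies(i)
        if qs.isSetMaxLevel() and qs.getMaxLevel() > 1:
            raise UnsupportedFormalismError(
                f"species {qs.getId()!r} has max level {qs.getMaxLevel()}; "
                "only strictly Boolean models are supported")
        components.append(qs.getId())
        if qs.isSetName():
            names[qs.getId()] = qs.getName()

    rules = {c: Var(c) for c in components}
    seen_targets = set()
    for i in range(qual.getNumTransitions()):
        tr = qual.getTransition(i)
        expr = _compile_transition(tr)
        for j in range(tr.getNumOutputs()):
            target = tr.getOutput(j).getQualitativeSpecies()
            if target in seen_targets:
                raise ValidationError(f"species {target!r} is the output of "
                                      "more than one transition")
            if target not in rules:
                raise ValidationError(f"transition output {target!r} is not a "
                                      "declared qualitative species")
            seen_targets.add(target)
            rules[target] = expr

    net = BooleanNetwork(tuple(components), rules, names)
    logger.info("loaded %s: %d components, %d inputs, %d interactions",
                path.name, len(net.components), len(net.inputs), net.n_interactions)
    return net


def _compile_transition(tr) -> LogicExpr:
    default = tr.getDefaultTerm()
    if default is None or not default.isSetResultLevel():
        raise ValidationError(f"transition {tr.getId()!r} has no default term")
    levels = [default.getResultLevel()]
    expr = Const(default.getResultLevel())
    # fold terms right-to-left: value = t1 ? r1 : (t2 ? r2 : ... : default)
    for k in range(tr.getNumFunctionTerms() - 1, -1, -1):
        ft = tr.getFunctionTerm(k)
        levels.append(ft.getResultLevel())
        cond = _ast_to_expr(ft.getMath())
        r = ft.getResultLevel()
        expr = Or((And((cond, Const(r))), And((Not(cond), expr)))).simplified()
    if any(lv not in (0, 1) for lv in levels):
        raise UnsupportedFormalismError(
            f"transition {tr.getId()!r} has result level outside {{0,1}}")
    return expr


def write_regulatory_model(net: BooleanNetwork, path) -> None:
    """Write a network back to SBML-qual (Level 3, qual version 1).

    Inputs (identity rules) are written as species without transitions;
    every other component gets one transition with a single result-1
    function term and a default of 0.
    """
    ns = libsbml.SBMLNamespaces(3, 1, "qual", 1)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("qual", True)
    model = doc.createModel()
    model.setId("regulatory_model")
    comp = model.createCompartment()
    comp.setId("default")
    comp.setConstant(True)
    qual = model.getPlugin("qual")

    for c in net.components:
        qs = qual.createQualitativeSpecies()
        qs.setId(c)
        qs.setCompartment("default")
        qs.setConstant(False)
        qs.setMaxLevel(1)
        if c in net.names:
            qs.setName(net.names[c])

    for c in net.components:
        rule = net.rules[c]
        if rule == Var(c):
            continue  # input: no transition
        tr = qual.createTransition()
        tr.setId(f"tr_{c}")
        for reg in sorted(rule.support()):
            inp = tr.createInput()
            inp.setQualitativeSpecies(reg)
            inp.setTransitionEffect(libsbml.INPUT_TRANSITION_EFFECT_NONE)
        out = tr.createOutput()
        out.setQualitativeSpecies(c)
        out.setTransitionEffect(libsbml.OUTPUT_TRANSITION_EFFECT_ASSIGNMENT_LEVEL)
        dt = tr.createDefaultTerm()
        dt.setResultLevel(0)
        ft = tr.createFunctionTerm()
        ft.setResultLevel(1)
        math = libsbml.parseL3Formula(_expr_to_l3(rule))
        if math is None:
            raise ValidationError(f"cannot serialize rule of {c!r}: {rule}")
        ft.setMath(math)

    if libsbml.writeSBMLToFile(doc, str(path)) != 1:
        raise IOError(f"failed to write SBML-qual to {path}")


def load_condition(path, label: str | None = None) -> Condition:
    """Read a flat ``name: value`` YAML/key-value file into a
    :class:`Condition`.  Values must be binary; resolution against a network
    happens separately via :meth:`Condition.resolve`."""
    path = Path(path)
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as e:
        raise ParseError(f"cannot parse condition file {path}: {e}") from e
    if data is None:
        data = {}
    if not isinstance(data, dict):
        raise ValidationError(f"{path} must be a flat name: value mapping")
    assignments = {}
    for k, v in data.items():
        if isinstance(v, bool):
            v = int(v)
        if v not in (0, 1):
            raise ValidationError(
                f"condition value for {k!r} must be 0 or 1, got {v!r}")
        assignments[str(k)] = v
    return Condition(assignments, label if label is not None else path.stem)
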