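"""Exception hierarchy for hybridra.

Every error raised on a user-facing path derives from :class:`HybridraError`
so callers (and the CLI) can catch one base class.
"""


class HybridraError(Exception):
    """Base class for all hybridra errors."""


class ParseError(HybridraError):
    """A file could not be parsed (malformed XML, bad syntax)."""


class UnsupportedFormalismError(HybridraError):
    """The input uses a formalism outside strictly Boolean logic
    (e.g. a qualitative species with maximum level > 1)."""


class ValidationError(HybridraError):
    """Structurally parseable input that violates a model invariant
    (undeclared species, non-binary condition value, lb > ub, ...)."""


class ResolutionError(HybridraError):
    """A name could not be resolved against a model; carries near-matches."""

    def __init__(self, message: str, near_matches=()):
        super().__init__(message)
        self.near_matches = tuple(near_matches)


class ContradictionError(HybridraError):
    """A component was fixed to both 0 and 1 by the caller."""


class BudgetExceededError(HybridraError):
    """A configurable resource cap (enumeration size, search nodes) was hit.

    Raised instead of returning a silent partial answer.
    """


class AmbiguousMappingError(HybridraError):
    """A regulatory component name matches both a metabolite and a
    reaction; mapping refuses to guess."""


class FormulaError(HybridraError):
    """An elemental formula string could not be parsed."""


class IntegrityError(HybridraError):
    """Cross-referenced objects disagree (e.g. a constraint names a
    reaction absent from the metabolic model)."""


class UndefinedFractionError(HybridraError):
    """ATP-source fractions are undefined because the objective value is 0."""
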