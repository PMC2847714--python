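"""Exception hierarchy.

Every data-level failure raises a subclass of :class:`PhenoXPError` so that
callers (and the CLI) can distinguish usage errors from malformed inputs.
"""


class PhenoXPError(Exception):
    """Base class for all package-specific errors."""


class MalformedDocumentError(PhenoXPError):
    """OBO text violates the supported format subset (e.g. duplicate ids)."""


class DefinitionArityError(PhenoXPError):
    """A stanza carries exactly one intersection_of clause.

    A genus-differentia definition needs a genus and at least one
    differentium, so a single clause can never be a complete definition.
    """


class MergeConflictError(PhenoXPError):
    """Two documents define the same id with conflicting stanza content."""


class NotAnEQDefinitionError(PhenoXPError):
    """Intersection clauses do not follow the Q + inheres_in E pattern."""


class UnsupportedPatternError(PhenoXPError):
    """A differentium uses a relation outside the EQ translation table."""


class GenusNotAQualityError(PhenoXPError):
    """Strict mode: the genus is not a descendant of the quality root."""


class AmbiguousCompositionError(PhenoXPError):
    """EW given while the entity is already a composed expression."""


class IncompleteDescriptionError(PhenoXPError):
    """EQ text record lacks a mandatory E or Q line."""


class EQSyntaxError(PhenoXPError):
    """Malformed EQ line syntax (e.g. unbalanced caret composition)."""

    def __init__(self, message: str, offset: int | None = None):
        super().__init__(message if offset is None else f"{message} (at offset {offset})")
        self.offset = offset


class UnsupportedCardinalityError(PhenoXPError):
    """Cardinality form requested for a relative number-of-parts quality."""


class CycleError(PhenoXPError):
    """The asserted is_a graph contains a cycle among distinct classes."""

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__("is_a cycle: " + " -> ".join(self.cycle + [self.cycle[0]]))


class UnknownClassError(PhenoXPError):
    """A query referenced an identifier absent from the closure."""


class EmptyReportError(PhenoXPError):
    """Recapitulation requested on an empty phenotype document."""


class GenerationError(PhenoXPError):
    """Random-suite parameters are infeasible for the requested sizes."""
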