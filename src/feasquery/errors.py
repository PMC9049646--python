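"""Exception hierarchy.

Every error raised by this package derives from :class:`FeasQueryError`,
so callers (and the CLI) can distinguish domain failures from bugs.
"""

from __future__ import annotations


class FeasQueryError(Exception):
    """Base class for all errors raised by feasquery."""


# --- conformance-artifact parsing -------------------------------------------

class ArtifactParseError(FeasQueryError):
    """A FHIR conformance document is malformed; the message names the field."""


class UnsupportedDocumentError(ArtifactParseError):
    """Document is not of the expected FHIR resourceType."""


class CyclicHierarchyError(ArtifactParseError):
    """A CodeSystem is-a relation contains a cycle.

    The offending cycle (one of possibly several) is stored in ``cycle``.
    """

    def __init__(self, cycle: list[str]):
        self.cycle = cycle
        super().__init__(
            "cyclic is-a hierarchy: " + " -> ".join(cycle + [cycle[0]])
        )


class ElementNotFoundError(FeasQueryError):
    """A profile element path does not resolve."""


# --- terminology -------------------------------------------------------------

class MissingCodeSystemError(FeasQueryError):
    """A ValueSet names a system absent from the registry."""


class UnknownCodeError(FeasQueryError):
    """A code (e.g. an is-a filter anchor) is absent from its system."""


class ExpansionError(FeasQueryError):
    """A terminology server returned an OperationOutcome for $expand."""


class TransportError(FeasQueryError):
    """A retryable network failure while talking to a terminology server."""


# --- ontology generation ------------------------------------------------------

class UnsupportedResourceTypeError(FeasQueryError):
    """No default handler and no corner case covers this resource type."""


class GenerationError(FeasQueryError):
    """UI-profile generation failed for a criterion (e.g. missing binding)."""


# --- mapping ------------------------------------------------------------------

class MissingSearchParameterError(FeasQueryError):
    """No standard and no custom search parameter registered for a path."""


class MappingConflictError(FeasQueryError):
    """Two profiles produced mapping entries for the same TermCode key."""


class UnmappedCriterionError(FeasQueryError):
    """A query criterion's code has no mapping entry."""


# --- structured query / translation ------------------------------------------

class SqParseError(FeasQueryError):
    """An SQ document violates the wire schema.

    ``pointer`` holds a JSON-pointer-style location of the first violation.
    """

    def __init__(self, message: str, pointer: str = ""):
        self.pointer = pointer
        super().__init__(f"{message} (at {pointer or '/'})")


class SqValidationError(FeasQueryError):
    """A StructuredQuery model violates its semantic invariants."""


class HeterogeneousExpansionError(FeasQueryError):
    """Expanded codes of one criterion span incompatible mapping entries."""


class TranslationError(FeasQueryError):
    """A criterion cannot be rendered into the target query language."""


# --- evaluation ---------------------------------------------------------------

class EvaluationError(FeasQueryError):
    """A search filter references a parameter absent from the store schema."""
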