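"""The Structured Query (SQ): the intermediate feasibility-query format.

A feasibility query travels from the query-builder UI to the translation
backend as a small JSON document with two parts:

* ``inclusion`` — conjunctive normal form: an AND over clauses, each clause
  an OR over criteria;
* ``exclusion`` — disjunctive normal form: an OR over clauses, each clause
  an AND over criteria.

The cohort is ``inclusion AND NOT exclusion``.  Both parts are negation-free
by construction: the wire format has no negation field anywhere, so the only
negation in the whole algebra is the single AND-NOT combining the parts.

A criterion names one or more alternative concept codes and an optional
value filter (a concept choice, or a quantity comparison or range).  No
hierarchy is transferred: a non-leaf criterion is widened to its descendants
at the site, via the terminology tree.

The wire schema is this package's own (version tag ``feasquery-sq-1``); it
documents the format locally and is shipped as JSON Schema alongside the
package.
"""

from __future__ import annotations

import json
from typing import Annotated, Any, Literal, Union

from pydantic import (
    BaseModel,
    ConfigDict,
    Field,
    ValidationError,
    model_validator,
)

from .artifacts import TermCode
from .errors import SqParseError, SqValidationError

__all__ = [
    "SQ_VERSION",
    "WireTermCode",
    "ConceptFilter",
    "QuantityComparatorFilter",
    "QuantityRangeFilter",
    "ValueFilter",
    "CriterionClause",
    "StructuredQuery",
    "validate_sq",
    "parse_sq",
    "serialize_sq",
]

SQ_VERSION = "feasquery-sq-1"

COMPARATORS = ("eq", "ne", "le", "ge", "lt", "gt")
Comparator = Literal["eq", "ne", "le", "ge", "lt", "gt"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", populate_by_name=True)


class WireTermCode(_Strict):
    system: str = Field(min_length=1)
    code: str = Field(min_length=1)
    display: str = ""
    version: str | None = None

    def to_term_code(self) -> TermCode:
        return TermCode(
            system=self.system, code=self.code,
            display=self.display, version=self.version,
        )

    @classmethod
    def from_term_code(cls, tc: TermCode) -> "WireTermCode":
        return cls(
            system=tc.system, code=tc.code,
            display=tc.display, version=tc.version,
        )


class ConceptFilter(_Strict):
    kind: Literal["concept"] = "concept"
    selected_concepts: list[WireTermCode] = Field(
        alias="selectedConcepts", min_length=1
    )


class QuantityComparatorFilter(_Strict):
    kind: Literal["quantity-comparator"] = "quantity-comparator"
    comparator: Comparator
    value: float
    unit: str = Field(min_length=1)


class QuantityRangeFilter(_Strict):
    kind: Literal["quantity-range"] = "quantity-range"
    min_value: float = Field(alias="minValue")
    max_value: float = Field(alias="maxValue")
    unit: str = Field(min_length=1)

    @model_validator(mode="after")
    def _ordered(self) -> "QuantityRangeFilter":
        if self.min_value > self.max_value:
            raise ValueError(
                f"range minimum {self.min_value} exceeds maximum "
                f"{self.max_value}"
            )
        return self


ValueFilter = Annotated[
    Union[ConceptFilter, QuantityComparatorFilter, QuantityRangeFilter],
    Field(discriminator="kind"),
]


class CriterionClause(_Strict):
    """One criterion: alternative codes for the same concept, plus an
    optional value restriction."""

    term_codes: list[WireTermCode] = Field(alias="termCodes", min_length=1)
    value_filter: ValueFilter | None = Field(alias="valueFilter", default=None)


class StructuredQuery(_Strict):
    version: Literal["feasquery-sq-1"] = SQ_VERSION
    inclusion: list[list[CriterionClause]]
    exclusion: list[list[CriterionClause]] = Field(default_factory=list)


def validate_sq(sq: StructuredQuery) -> list[str]:
    """Semantic checks beyond the wire schema; an empty report is valid.

    A feasibility query must include someone, so empty inclusion is a
    violation; empty exclusion simply excludes nobody.
    """
    report: list[str] = []
    if not sq.inclusion:
        report.append("inclusion must be non-empty")
    for part, clauses in (("inclusion", sq.inclusion),
                          ("exclusion", sq.exclusion)):
        for i, clause in enumerate(clauses):
            if not clause:
                report.append(f"{part}[{i}] is an empty clause")
            for j, criterion in enumerate(clause):
                vf = criterion.value_filter
                if (
                    isinstance(vf, QuantityRangeFilter)
                    and vf.min_value > vf.max_value
                ):
                    report.append(
                        f"{part}[{i}][{j}]: range minimum exceeds maximum"
                    )
    return report


def _pointer(loc: tuple[Any, ...]) -> str:
    return "/" + "/".join(str(part) for part in loc)


def parse_sq(doc: dict[str, Any] | str | bytes) -> StructuredQuery:
    """Parse and schema-validate an SQ document; unknown fields are
    rejected.  Errors carry a JSON-pointer location."""
    if isinstance(doc, (str, bytes)):
        try:
            doc = json.loads(doc)
        except json.JSONDecodeError as exc:
            raise SqParseError(f"not valid JSON: {exc}") from exc
    try:
        return StructuredQuery.model_validate(doc)
    except ValidationError as exc:
        first = exc.errors()[0]
        raise SqParseError(first["msg"], pointer=_pointer(first["loc"])) from exc


def serialize_sq(sq: StructuredQuery) -> dict[str, Any]:
    """Canonical JSON form; refuses semantically invalid queries.

    Key order is fixed by the model definition, so repeated serialization
    of equal queries is byte-identical after ``json.dumps``.
    """
    report = validate_sq(sq)
    if report:
        raise SqValidationError("; ".join(report))
    return sq.model_dump(by_alias=True, exclude_none=True)
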