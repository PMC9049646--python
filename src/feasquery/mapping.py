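"""Criterion mapping and terminology tree generation.

The UI profiles deliberately carry no information about the FHIR data model
or the query languages, and the Structured Query carries no hierarchy.  Two
generated artifacts reintroduce that information at translation time:

* the *mapping* — one entry per selectable criterion code, keyed by
  ``(system, code)``, recording the ResourceType, the search parameter and
  FHIR path of the criterion code, those of its optional value, and the
  *fixed criteria* that silently constrain every query for the criterion
  (e.g. only verified conditions are searched);
* the *terminology tree* — the UI profiles stripped to codes and child
  lists, which lets a site resolve a non-leaf criterion to itself plus all
  descendants without running a terminology server.

Element paths that lack a standard R4 search parameter (extensions,
component slices, ``value[integer]``) resolve through a registry of custom
search parameters, which can also be emitted as FHIR ``SearchParameter``
resources for server registration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Any, Iterator, Mapping, Sequence

from .artifacts import ProfileModel, TermCode, element_by_path
from .errors import (
    MappingConflictError,
    MissingSearchParameterError,
    UnmappedCriterionError,
)
from .ontology import (
    CategoryTree,
    HandlerSpec,
    UIProfileNode,
    classify_profile,
    iter_selectable_nodes,
)
from .systems import CONDITION_VER_STATUS

__all__ = [
    "FixedCriterion",
    "MappingEntry",
    "CriterionMapping",
    "TermTreeNode",
    "SearchParameterRegistry",
    "resolve_search_parameter",
    "generate_mapping",
    "generate_term_tree",
    "lookup_map_entry",
    "tree_descendants",
]


CONFIRMED = TermCode(
    system=CONDITION_VER_STATUS, code="confirmed", display="Confirmed"
)


@dataclass(frozen=True)
class FixedCriterion:
    """A predefined constraint appended to every query for a criterion."""

    search_parameter: str
    fhir_path: str
    values: tuple[TermCode, ...]

    def __post_init__(self) -> None:
        if not self.values:
            raise ValueError("fixed criterion without values")

    def to_json(self) -> dict[str, Any]:
        return {
            "searchParameter": self.search_parameter,
            "fhirPath": self.fhir_path,
            "values": [v.to_json() for v in self.values],
        }

    @classmethod
    def from_json(cls, doc: dict[str, Any]) -> "FixedCriterion":
        return cls(
            search_parameter=doc["searchParameter"],
            fhir_path=doc["fhirPath"],
            values=tuple(TermCode.from_json(v) for v in doc["values"]),
        )


@dataclass(frozen=True)
class MappingEntry:
    """Everything needed to query one criterion code at a site."""

    key: TermCode
    resource_type: str
    term_code_search_parameter: str
    term_code_fhir_path: str
    value_search_parameter: str | None = None
    value_fhir_path: str | None = None
    value_kind: str = "none"
    fixed_criteria: tuple[FixedCriterion, ...] = ()

    def __post_init__(self) -> None:
        if (self.value_kind == "none") != (self.value_search_parameter is None):
            raise ValueError(
                f"entry {self.key.system}|{self.key.code}: value search "
                "parameter present iff value_kind is not 'none'"
            )
        for fc in self.fixed_criteria:
            if fc.search_parameter == self.value_search_parameter:
                raise ValueError(
                    f"entry {self.key.code}: fixed criterion reuses the "
                    f"value search parameter {fc.search_parameter!r}"
                )

    def to_json(self) -> dict[str, Any]:
        return {
            "key": self.key.to_json(),
            "resourceType": self.resource_type,
            "termCodeSearchParameter": self.term_code_search_parameter,
            "termCodeFhirPath": self.term_code_fhir_path,
            "valueSearchParameter": self.value_search_parameter,
            "valueFhirPath": self.value_fhir_path,
            "valueKind": self.value_kind,
            "fixedCriteria": [fc.to_json() for fc in self.fixed_criteria],
        }

    @classmethod
    def from_json(cls, doc: dict[str, Any]) -> "MappingEntry":
        return cls(
            key=TermCode.from_json(doc["key"]),
            resource_type=doc["resourceType"],
            term_code_search_parameter=doc["termCodeSearchParameter"],
            term_code_fhir_path=doc["termCodeFhirPath"],
            value_search_parameter=doc.get("valueSearchParameter"),
            value_fhir_path=doc.get("valueFhirPath"),
            value_kind=doc.get("valueKind", "none"),
            fixed_criteria=tuple(
                FixedCriterion.from_json(fc)
                for fc in doc.get("fixedCriteria", [])
            ),
        )


class CriterionMapping:
    """The full mapping, keyed by ``(system, code)`` (version-insensitive)."""

    def __init__(self, entries: Sequence[MappingEntry] = ()):
        self._by_key: dict[tuple[str, str], MappingEntry] = {}
        for entry in entries:
            self.add(entry)

    def add(self, entry: MappingEntry) -> None:
        existing = self._by_key.get(entry.key.key)
        if existing is not None:
            raise MappingConflictError(
                f"duplicate mapping key {entry.key.system}|{entry.key.code}: "
                f"paths {existing.term_code_fhir_path!r} and "
                f"{entry.term_code_fhir_path!r}"
            )
        self._by_key[entry.key.key] = entry

    def __len__(self) -> int:
        return len(self._by_key)

    def __iter__(self) -> Iterator[MappingEntry]:
        return iter(self._by_key.values())

    def __contains__(self, tc: TermCode) -> bool:
        return tc.key in self._by_key

    def lookup(self, tc: TermCode) -> MappingEntry:
        entry = self._by_key.get(tc.key)
        if entry is None:
            raise UnmappedCriterionError(
                f"no mapping entry for {tc.system}|{tc.code}"
            )
        return entry

    def to_json(self) -> dict[str, Any]:
        entries = sorted(self._by_key.values(), key=lambda e: e.key.key)
        return {"entries": [e.to_json() for e in entries]}

    @classmethod
    def from_json(cls, doc: dict[str, Any]) -> "CriterionMapping":
        return cls([MappingEntry.from_json(e) for e in doc["entries"]])


def lookup_map_entry(mapping: CriterionMapping, tc: TermCode) -> MappingEntry:
    """Entry whose key equals ``tc`` by ``(system, code)``."""
    return mapping.lookup(tc)


@dataclass
class TermTreeNode:
    """A terminology-tree node: exactly a code and its children."""

    term_code: TermCode
    children: list["TermTreeNode"] = field(default_factory=list)

    def to_json(self) -> dict[str, Any]:
        return {
            "termCode": {
                "system": self.term_code.system,
                "code": self.term_code.code,
            },
            "children": [c.to_json() for c in self.children],
        }

    @classmethod
    def from_json(cls, doc: dict[str, Any]) -> "TermTreeNode":
        return cls(
            term_code=TermCode(
                system=doc["termCode"]["system"],
                code=doc["termCode"]["code"],
                display=doc["termCode"]["code"],
            ),
            children=[cls.from_json(c) for c in doc.get("children", [])],
        )


def tree_descendants(
    roots: Sequence[TermTreeNode], tc: TermCode
) -> set[TermCode] | None:
    """Self plus all descendants of ``tc`` in the tree, or ``None`` if the
    code does not occur.  A code occurring several times (multi-parent
    duplication) contributes the union of its subtrees."""
    found: set[TermCode] | None = None

    def collect(node: TermTreeNode) -> set[TermCode]:
        out = {node.term_code}
        for child in node.children:
            out |= collect(child)
        return out

    def walk(node: TermTreeNode) -> None:
        nonlocal found
        if node.term_code == tc:
            found = (found or set()) | collect(node)
        for child in node.children:
            walk(child)

    for root in roots:
        walk(root)
    return found


# ---------------------------------------------------------------------------
# search parameters


class SearchParameterRegistry:
    """Standard R4 plus custom search parameters, keyed by (type, path)."""

    def __init__(
        self,
        standard: Mapping[tuple[str, str], str],
        custom: Mapping[tuple[str, str], str],
        custom_types: Mapping[tuple[str, str], str] | None = None,
    ):
        self._standard = dict(standard)
        self._custom = dict(custom)
        self._custom_types = dict(custom_types or {})

    @classmethod
    def _load_file(cls, text: str) -> tuple[dict, dict]:
        doc = json.loads(text)
        params = {
            (p["resourceType"], p["path"]): p["name"]
            for p in doc["parameters"]
        }
        types = {
            (p["resourceType"], p["path"]): p.get("type", "token")
            for p in doc["parameters"]
        }
        return params, types

    @classmethod
    def load_default(cls, extra_custom_file: str | Path | None = None
                     ) -> "SearchParameterRegistry":
        data = importlib_resources.files("feasquery") / "data"
        standard, _ = cls._load_file(
            (data / "standard_search_parameters.json").read_text("utf-8")
        )
        custom, ctypes = cls._load_file(
            (data / "custom_search_parameters.json").read_text("utf-8")
        )
        if extra_custom_file is not None:
            more, more_types = cls._load_file(
                Path(extra_custom_file).read_text("utf-8")
            )
            custom.update(more)
            ctypes.update(more_types)
        return cls(standard, custom, ctypes)

    def resolve(self, resource_type: str, path: str) -> tuple[str, bool]:
        name = self._standard.get((resource_type, path))
        if name is not None:
            return name, False
        name = self._custom.get((resource_type, path))
        if name is not None:
            return name, True
        raise MissingSearchParameterError(
            f"no standard or custom search parameter for "
            f"{resource_type} path {path!r}"
        )

    def path_for(self, resource_type: str, name: str) -> str:
        """Inverse lookup used by the in-memory evaluator."""
        for (rt, path), pname in {**self._standard, **self._custom}.items():
            if rt == resource_type and pname == name:
                return path
        raise MissingSearchParameterError(
            f"no registered path for {resource_type} parameter {name!r}"
        )

    def custom_parameter_resources(self) -> list[dict[str, Any]]:
        """FHIR SearchParameter resources for the custom parameters."""
        out = []
        for (rt, path), name in sorted(self._custom.items()):
            out.append({
                "resourceType": "SearchParameter",
                "url": f"http://feasquery.local/SearchParameter/{name}",
                "name": name,
                "status": "active",
                "code": name,
                "base": [rt],
                "type": self._custom_types.get((rt, path), "token"),
                "expression": path.replace(":", "."),
                "description": f"Custom parameter for {rt} {path}",
            })
        return out


_DEFAULT_REGISTRY: SearchParameterRegistry | None = None


def _default_registry() -> SearchParameterRegistry:
    global _DEFAULT_REGISTRY
    if _DEFAULT_REGISTRY is None:
        _DEFAULT_REGISTRY = SearchParameterRegistry.load_default()
    return _DEFAULT_REGISTRY


def resolve_search_parameter(
    resource_type: str,
    element_path: str,
    registry: SearchParameterRegistry | None = None,
) -> tuple[str, bool]:
    """Search parameter for an element path; the flag marks custom ones."""
    registry = registry or _default_registry()
    return registry.resolve(resource_type, element_path)


# ---------------------------------------------------------------------------
# mapping generation


def _component_code_path(value_attr: str) -> str:
    # "Observation.component:systolic.value[x]" -> ".../code"
    stem = value_attr.rsplit(".", 1)[0]
    return stem + ".code"


def _fixed_criteria_for(
    profile: ProfileModel,
    handler: HandlerSpec,
    registry: SearchParameterRegistry,
    condition_fixed: Mapping[str, tuple[TermCode, ...]],
) -> tuple[FixedCriterion, ...]:
    fixed: list[FixedCriterion] = []
    if handler.resource_type == "Condition":
        values = condition_fixed.get(profile.name, (CONFIRMED,))
        if values:
            name, _ = registry.resolve("Condition", "Condition.verificationStatus")
            fixed.append(FixedCriterion(
                search_parameter=name,
                fhir_path="Condition.verificationStatus",
                values=values,
            ))
    if handler.value_kind in ("component-concept", "component-quantity"):
        code_path = _component_code_path(handler.value_attr or "")
        component_el = element_by_path(profile, code_path)
        if component_el.fixed_value is None:
            raise MissingSearchParameterError(
                f"profile {profile.name!r}: component code at {code_path!r} "
                "has no fixed value"
            )
        name, _ = registry.resolve(handler.resource_type, code_path)
        fv = component_el.fixed_value
        fixed.append(FixedCriterion(
            search_parameter=name,
            fhir_path=code_path,
            values=(TermCode(
                system=fv["system"], code=fv["code"],
                display=fv.get("display", fv["code"]),
            ),),
        ))
    return tuple(fixed)


def generate_mapping(
    categories: Sequence[CategoryTree],
    profiles: Mapping[str, ProfileModel],
    handlers: Mapping[str, HandlerSpec] | None = None,
    registry: SearchParameterRegistry | None = None,
    condition_fixed: Mapping[str, tuple[TermCode, ...]] | None = None,
) -> CriterionMapping:
    """One mapping entry per selectable UI-profile code.

    Group nodes carry the profile name as their code, which re-associates
    every selectable descendant with its source profile and handler.  A code
    emitted by two profiles is a hard conflict: ambiguous translation is
    worse than failed generation.
    """
    registry = registry or _default_registry()
    condition_fixed = condition_fixed or {}
    mapping = CriterionMapping()
    for tree in categories:
        for group in tree.roots:
            profile = profiles.get(group.term_code.code)
            if profile is None:
                continue
            handler = classify_profile(profile, handlers)
            term_el = element_by_path(profile, handler.criterion_attr)
            term_param, _ = registry.resolve(profile.resource_type, term_el.path)
            value_param = value_path = None
            if handler.value_kind != "none":
                value_el = element_by_path(profile, handler.value_attr)  # type: ignore[arg-type]
                value_param, _ = registry.resolve(
                    profile.resource_type, value_el.path
                )
                value_path = value_el.path
            fixed = _fixed_criteria_for(
                profile, handler, registry, condition_fixed
            )
            for node in iter_selectable_nodes([CategoryTree("", [group])]):
                mapping.add(MappingEntry(
                    key=node.term_code,
                    resource_type=profile.resource_type,
                    term_code_search_parameter=term_param,
                    term_code_fhir_path=term_el.path,
                    value_search_parameter=value_param,
                    value_fhir_path=value_path,
                    value_kind=handler.value_kind,
                    fixed_criteria=fixed,
                ))
    return mapping


def generate_term_tree(
    categories: Sequence[CategoryTree],
) -> list[TermTreeNode]:
    """Project every UI node to ``{term_code, children}``, dropping display
    and value information."""
    def project(node: UIProfileNode) -> TermTreeNode:
        return TermTreeNode(
            term_code=node.term_code,
            children=[project(c) for c in node.children],
        )

    return [project(root) for tree in categories for root in tree.roots]
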