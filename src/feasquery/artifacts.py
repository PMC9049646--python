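"""Reading and modeling FHIR R4 conformance resources.

The generator pipeline is driven by four kinds of conformance artifacts,
all consumed as JSON documents:

* ``StructureDefinition`` profiles constraining a base Resource — each is a
  blueprint of the instance data held at a clinical site;
* a ``LogicalModel`` (also a StructureDefinition, ``kind: logical``) whose
  first-level elements name the criterion categories and whose second-level
  elements name the criteria, each criterion name identifying a profile;
* ``CodeSystem`` resources carrying concepts and their is-a relations;
* ``ValueSet`` resources selecting concepts from those systems.

Only the fields that drive ontology generation are modeled: element paths,
ValueSet bindings, fixed values, concept hierarchies and compose rules.
This is deliberately not a FHIR validator.

Choice-type element paths (``value[x]``) are normalized at parse time to the
concrete typed path (``valueQuantity``) whenever the element constrains a
single type, so downstream path lookups never deal with ``[x]``.
All artifact I/O is UTF-8.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Iterable, Iterator

from .errors import (
    ArtifactParseError,
    CyclicHierarchyError,
    ElementNotFoundError,
    UnsupportedDocumentError,
)

__all__ = [
    "TermCode",
    "ElementModel",
    "ProfileModel",
    "CategorySpec",
    "CodeSystemModel",
    "IncludeRule",
    "ValueSetModel",
    "ArtifactSet",
    "parse_structure_definition",
    "parse_logical_model",
    "parse_code_system",
    "parse_value_set",
    "element_by_path",
    "load_artifact_directory",
]


@dataclass(frozen=True)
class TermCode:
    """A ``(system, code)`` pair identifying one concept — the criterion key.

    Equality and hashing use only ``system`` and ``code``: the mapping is
    keyed by that pair, and display texts and system versions drift between
    releases of the same terminology.  ``display`` and ``version`` are
    carried for diagnostics and UI labels only.
    """

    system: str
    code: str
    display: str = ""
    version: str | None = None

    def __post_init__(self) -> None:
        if not self.system or not self.code:
            raise ValueError("TermCode requires non-empty system and code")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TermCode):
            return NotImplemented
        return self.system == other.system and self.code == other.code

    def __hash__(self) -> int:
        return hash((self.system, self.code))

    @property
    def key(self) -> tuple[str, str]:
        return (self.system, self.code)

    def to_json(self) -> dict[str, Any]:
        doc: dict[str, Any] = {
            "system": self.system,
            "code": self.code,
            "display": self.display,
        }
        if self.version is not None:
            doc["version"] = self.version
        return doc

    @classmethod
    def from_json(cls, doc: dict[str, Any]) -> "TermCode":
        return cls(
            system=doc["system"],
            code=doc["code"],
            display=doc.get("display", ""),
            version=doc.get("version"),
        )


@dataclass(frozen=True)
class ElementModel:
    """One element definition of a profile.

    ``path`` is the dotted (slice-qualified) element path, e.g.
    ``Condition.code`` or ``Patient.extension:age.valueQuantity``.
    """

    path: str
    type_code: str = ""
    binding_url: str | None = None
    fixed_value: Any = None

    def __post_init__(self) -> None:
        if self.binding_url is not None and ":" not in self.binding_url.split("|")[0]:
            raise ArtifactParseError(
                f"element {self.path!r}: binding URL {self.binding_url!r} "
                "is not a valid URI"
            )


@dataclass
class ProfileModel:
    """A parsed StructureDefinition profile."""

    url: str
    name: str
    resource_type: str
    elements: list[ElementModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.resource_type:
            raise ArtifactParseError(f"profile {self.name!r}: empty resource type")
        paths = [e.path for e in self.elements]
        if len(paths) != len(set(paths)):
            dupes = sorted({p for p in paths if paths.count(p) > 1})
            raise ArtifactParseError(
                f"profile {self.name!r}: duplicate element paths {dupes}"
            )

    def to_structure_definition(self) -> dict[str, Any]:
        """Serialize the modeled fields back to a snapshot StructureDefinition."""
        elements: list[dict[str, Any]] = []
        for el in self.elements:
            plain_path = re.sub(r":[^.]+", "", el.path)  # strip slice names
            entry: dict[str, Any] = {"id": el.path, "path": plain_path}
            if el.type_code:
                entry["type"] = [{"code": el.type_code}]
            if el.binding_url is not None:
                entry["binding"] = {"strength": "required", "valueSet": el.binding_url}
            if el.fixed_value is not None:
                suffix = el.type_code[:1].upper() + el.type_code[1:] if el.type_code else "String"
                entry[f"fixed{suffix}"] = el.fixed_value
            elements.append(entry)
        return {
            "resourceType": "StructureDefinition",
            "url": self.url,
            "name": self.name,
            "status": "active",
            "kind": "resource",
            "abstract": False,
            "type": self.resource_type,
            "snapshot": {"element": elements},
        }


@dataclass
class CategorySpec:
    """One UI category from the LogicalModel with its criterion names."""

    name: str
    criterion_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.name:
            raise ArtifactParseError("category with empty name")
        if len(self.criterion_names) != len(set(self.criterion_names)):
            raise ArtifactParseError(
                f"category {self.name!r}: duplicate criterion names"
            )


@dataclass
class CodeSystemModel:
    """A code system: concepts plus is-a assertions (child -> parent)."""

    url: str
    concepts: dict[str, str] = field(default_factory=dict)  # code -> display
    parent_edges: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for child, parent in self.parent_edges:
            if child == parent:
                raise CyclicHierarchyError([child])
            for code in (child, parent):
                if code not in self.concepts:
                    raise ArtifactParseError(
                        f"code system {self.url}: edge endpoint {code!r} "
                        "is not a concept"
                    )
        _assert_acyclic(self.parent_edges)

    def parents_of(self, code: str) -> list[str]:
        return [p for c, p in self.parent_edges if c == code]

    def children_of(self, code: str) -> list[str]:
        return [c for c, p in self.parent_edges if p == code]

    def term_code(self, code: str) -> TermCode:
        return TermCode(system=self.url, code=code, display=self.concepts[code])

    def to_document(self) -> dict[str, Any]:
        """Serialize using parent properties (the flat hierarchy encoding)."""
        parents: dict[str, list[str]] = {}
        for child, parent in self.parent_edges:
            parents.setdefault(child, []).append(parent)
        concept_list = []
        for code, display in self.concepts.items():
            entry: dict[str, Any] = {"code": code, "display": display}
            props = [
                {"code": "parent", "valueCode": p} for p in parents.get(code, [])
            ]
            if props:
                entry["property"] = props
            concept_list.append(entry)
        return {
            "resourceType": "CodeSystem",
            "url": self.url,
            "status": "active",
            "content": "complete",
            "hierarchyMeaning": "is-a",
            "concept": concept_list,
        }


@dataclass(frozen=True)
class IncludeRule:
    """One compose.include of a ValueSet.

    Exactly one of three shapes: whole system (neither ``codes`` nor
    ``filter_anchor``), explicit code list, or an is-a filter anchored at a
    code whose transitive descendants are included.
    """

    system: str
    codes: tuple[str, ...] | None = None
    filter_anchor: str | None = None

    def __post_init__(self) -> None:
        if not self.system:
            raise ArtifactParseError("include rule without a system")
        if self.codes is not None and self.filter_anchor is not None:
            raise ArtifactParseError(
                f"include rule for {self.system}: explicit concept list and "
                "is-a filter are mutually exclusive"
            )


@dataclass
class ValueSetModel:
    url: str
    include_rules: list[IncludeRule] = field(default_factory=list)

    def to_document(self) -> dict[str, Any]:
        includes = []
        for rule in self.include_rules:
            inc: dict[str, Any] = {"system": rule.system}
            if rule.codes is not None:
                inc["concept"] = [{"code": c} for c in rule.codes]
            if rule.filter_anchor is not None:
                inc["filter"] = [
                    {"property": "concept", "op": "is-a", "value": rule.filter_anchor}
                ]
            includes.append(inc)
        return {
            "resourceType": "ValueSet",
            "url": self.url,
            "status": "active",
            "compose": {"include": includes},
        }


@dataclass
class ArtifactSet:
    """The full conformance input of one generation run."""

    categories: list[CategorySpec]
    profiles: dict[str, ProfileModel]  # keyed by profile name
    value_sets: dict[str, ValueSetModel]  # keyed by canonical URL
    code_systems: dict[str, CodeSystemModel]  # keyed by system URI


# ---------------------------------------------------------------------------
# parsing


def _require(doc: dict[str, Any], field_name: str, context: str) -> Any:
    if field_name not in doc:
        raise ArtifactParseError(f"{context}: missing field {field_name!r}")
    return doc[field_name]


def _check_resource_type(doc: Any, expected: str) -> None:
    if not isinstance(doc, dict) or "resourceType" not in doc:
        raise UnsupportedDocumentError(
            f"document has no resourceType (expected {expected!r})"
        )
    if doc["resourceType"] != expected:
        raise UnsupportedDocumentError(
            f"unsupported resourceType {doc['resourceType']!r} "
            f"(expected {expected!r})"
        )


_CHOICE_SUFFIX = "[x]"


def _normalize_choice_path(raw_path: str, types: list[dict[str, Any]]) -> str:
    # value[x] with a single constrained type becomes the typed path.
    if not raw_path.endswith(_CHOICE_SUFFIX) or len(types) != 1:
        return raw_path
    code = types[0].get("code", "")
    if not code:
        return raw_path
    stem = raw_path[: -len(_CHOICE_SUFFIX)]
    return stem + code[:1].upper() + code[1:]


def _parse_element(entry: dict[str, Any]) -> ElementModel:
    raw_path = entry.get("id") or _require(entry, "path", "element definition")
    types = entry.get("type", [])
    path = _normalize_choice_path(raw_path, types)
    type_code = types[0].get("code", "") if types else ""
    binding = entry.get("binding")
    binding_url = None
    if binding is not None:
        binding_url = _require(binding, "valueSet", f"binding of {path}")
        binding_url = binding_url.split("|")[0]  # strip version suffix
    fixed_value = None
    for key, value in entry.items():
        if key.startswith("fixed") or key.startswith("pattern"):
            fixed_value = value
            break
    return ElementModel(
        path=path, type_code=type_code, binding_url=binding_url,
        fixed_value=fixed_value,
    )


def parse_structure_definition(doc: dict[str, Any]) -> ProfileModel:
    """Parse a StructureDefinition profile into a :class:`ProfileModel`.

    The snapshot element list is preferred; the differential alone is
    accepted so that profiles need no snapshot generation step.
    """
    _check_resource_type(doc, "StructureDefinition")
    name = doc.get("name") or doc.get("id") or "<unnamed>"
    resource_type = _require(doc, "type", f"StructureDefinition {name!r}")
    view = doc.get("snapshot") or doc.get("differential")
    if view is None or "element" not in view:
        raise ArtifactParseError(
            f"StructureDefinition {name!r}: missing field "
            "'snapshot.element' or 'differential.element'"
        )
    elements = [_parse_element(entry) for entry in view["element"]]
    return ProfileModel(
        url=doc.get("url", ""),
        name=name,
        resource_type=resource_type,
        elements=elements,
    )


def parse_logical_model(doc: dict[str, Any]) -> list[CategorySpec]:
    """Parse the LogicalModel into ordered categories with criterion names.

    First-level elements (``Root.Category``) are categories; second-level
    elements (``Root.Category.Criterion``) are criteria whose names identify
    profiles.  Document order is preserved throughout.
    """
    _check_resource_type(doc, "StructureDefinition")
    view = doc.get("snapshot") or doc.get("differential")
    if view is None or "element" not in view:
        raise ArtifactParseError("LogicalModel: missing element list")
    categories: list[CategorySpec] = []
    by_name: dict[str, CategorySpec] = {}
    max_depth = 0
    for entry in view["element"]:
        path = _require(entry, "path", "LogicalModel element")
        parts = path.split(".")
        max_depth = max(max_depth, len(parts))
        if len(parts) == 2:
            spec = CategorySpec(name=parts[1])
            categories.append(spec)
            by_name[parts[1]] = spec
        elif len(parts) == 3:
            category = by_name.get(parts[1])
            if category is None:
                raise ArtifactParseError(
                    f"LogicalModel: criterion {path!r} precedes its category"
                )
            if parts[2] in category.criterion_names:
                raise ArtifactParseError(
                    f"LogicalModel: duplicate criterion {parts[2]!r} "
                    f"in category {parts[1]!r}"
                )
            category.criterion_names.append(parts[2])
    if categories and max_depth < 3:
        warnings.warn(
            "LogicalModel has no second-level elements; "
            "categories carry no criteria",
            stacklevel=2,
        )
    return categories


def _walk_nested_concepts(
    concepts: list[dict[str, Any]], parent: str | None
) -> Iterator[tuple[str, str, str | None]]:
    for entry in concepts:
        code = _require(entry, "code", "CodeSystem concept")
        yield code, entry.get("display", code), parent
        yield from _walk_nested_concepts(entry.get("concept", []), code)


def _assert_acyclic(edges: Iterable[tuple[str, str]]) -> None:
    parents: dict[str, list[str]] = {}
    for child, parent in edges:
        parents.setdefault(child, []).append(parent)

    WHITE, GREY, BLACK = 0, 1, 2
    color: dict[str, int] = {}

    def visit(node: str, stack: list[str]) -> None:
        color[node] = GREY
        stack.append(node)
        for nxt in parents.get(node, []):
            state = color.get(nxt, WHITE)
            if state == GREY:
                cycle = stack[stack.index(nxt):]
                raise CyclicHierarchyError(cycle)
            if state == WHITE:
                visit(nxt, stack)
        stack.pop()
        color[node] = BLACK

    for node in list(parents):
        if color.get(node, WHITE) == WHITE:
            visit(node, [])


def parse_code_system(doc: dict[str, Any]) -> CodeSystemModel:
    """Parse a CodeSystem; nested concepts and parent properties are
    equivalent hierarchy encodings and produce identical models."""
    _check_resource_type(doc, "CodeSystem")
    url = _require(doc, "url", "CodeSystem")
    concepts: dict[str, str] = {}
    edges: list[tuple[str, str]] = []
    for code, display, parent in _walk_nested_concepts(doc.get("concept", []), None):
        concepts[code] = display
        if parent is not None:
            edges.append((code, parent))
    # flat encoding: parent properties on top-level concepts
    for entry in doc.get("concept", []):
        code = entry["code"]
        for prop in entry.get("property", []):
            if prop.get("code") == "parent":
                edges.append((code, prop["valueCode"]))
    return CodeSystemModel(url=url, concepts=concepts, parent_edges=edges)


def parse_value_set(doc: dict[str, Any]) -> ValueSetModel:
    """Parse a ValueSet compose section into include rules."""
    _check_resource_type(doc, "ValueSet")
    url = _require(doc, "url", "ValueSet")
    compose = doc.get("compose")
    if compose is None:
        warnings.warn(f"ValueSet {url}: no compose section", stacklevel=2)
        return ValueSetModel(url=url, include_rules=[])
    rules: list[IncludeRule] = []
    for inc in compose.get("include", []):
        system = _require(inc, "system", f"ValueSet {url} include")
        codes: tuple[str, ...] | None = None
        anchor: str | None = None
        if "concept" in inc:
            codes = tuple(c["code"] for c in inc["concept"])
        for f in inc.get("filter", []):
            if f.get("op") == "is-a":
                anchor = f["value"]
            else:
                raise ArtifactParseError(
                    f"ValueSet {url}: unsupported filter op {f.get('op')!r}"
                )
        rules.append(IncludeRule(system=system, codes=codes, filter_anchor=anchor))
    return ValueSetModel(url=url, include_rules=rules)


def element_by_path(profile: ProfileModel, path: str) -> ElementModel:
    """Return the unique element with ``path``, resolving ``[x]`` choices.

    A choice path like ``Observation.value[x]`` matches the profile's
    normalized typed path (``Observation.valueQuantity``) when the profile
    constrains the choice to one type.
    """
    for el in profile.elements:
        if el.path == path:
            return el
    if path.endswith(_CHOICE_SUFFIX):
        stem = path[: -len(_CHOICE_SUFFIX)]
        matches = [
            el for el in profile.elements
            if el.path.startswith(stem) and el.path != stem
            and "." not in el.path[len(stem):]
            and el.path[len(stem): len(stem) + 1].isupper()
        ]
        if len(matches) == 1:
            return matches[0]
        if len(matches) > 1:
            raise ElementNotFoundError(
                f"profile {profile.name!r}: choice path {path!r} is ambiguous"
            )
    raise ElementNotFoundError(
        f"profile {profile.name!r}: no element at path {path!r}"
    )


# ---------------------------------------------------------------------------
# directory layout


def _read_json(path: Path) -> Any:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def load_artifact_directory(root: str | Path) -> ArtifactSet:
    """Load the conventional layout: ``profiles/``, ``valuesets/``,
    ``codesystems/`` and ``logicalmodel.json`` under ``root``."""
    root = Path(root)
    lm_path = root / "logicalmodel.json"
    if not lm_path.is_file():
        raise ArtifactParseError(f"missing {lm_path}")
    categories = parse_logical_model(_read_json(lm_path))
    profiles: dict[str, ProfileModel] = {}
    for p in sorted((root / "profiles").glob("*.json")):
        profile = parse_structure_definition(_read_json(p))
        profiles[profile.name] = profile
    value_sets: dict[str, ValueSetModel] = {}
    for p in sorted((root / "valuesets").glob("*.json")):
        vs = parse_value_set(_read_json(p))
        value_sets[vs.url] = vs
    code_systems: dict[str, CodeSystemModel] = {}
    for p in sorted((root / "codesystems").glob("*.json")):
        cs = parse_code_system(_read_json(p))
        code_systems[cs.url] = cs
    return ArtifactSet(
        categories=categories,
        profiles=profiles,
        value_sets=value_sets,
        code_systems=code_systems,
    )
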