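"""ValueSet expansion and subsumption forests.

A ValueSet is expanded into a flat set of :class:`TermCode` concepts, either
locally from a registry of parsed CodeSystems (the default — clinical sites
in a federated network frequently run no terminology server) or through a
FHIR ``ValueSet/$expand`` call against a server honoring the same contract.

The expansion is then shaped into a *subsumption forest*: the is-a hierarchy
of the expanded concepts, used both to display criteria as a tree and to
resolve a non-leaf criterion to itself plus all of its descendants at query
time.  Two subtleties:

* an expansion need not be closed under the is-a relation — when a concept's
  parent is absent from the expansion, the concept attaches to its *nearest
  expanded ancestor* (or becomes a root), which preserves subsumption
  semantics for query widening;
* the forest's edge set is the transitive reduction of the is-a closure
  restricted to the expansion, so no edge duplicates a longer is-a path.

Concepts with several parents inside the expansion keep all of them here
(the structure is a DAG); duplication under each parent happens when the
forest is rendered into the UI tree.
"""

from __future__ import annotations

import json
import urllib.error
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping

import networkx as nx

from .artifacts import CodeSystemModel, TermCode, ValueSetModel
from .errors import (
    ExpansionError,
    MissingCodeSystemError,
    TransportError,
    UnknownCodeError,
)

__all__ = [
    "Expansion",
    "SubsumptionForest",
    "expand_value_set",
    "build_subsumption_forest",
    "descendants",
    "TerminologyClient",
    "remote_expand",
]


@dataclass
class Expansion:
    """The flat concept set of one expanded ValueSet (no duplicates)."""

    value_set_url: str
    concepts: list[TermCode] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        unique: list[TermCode] = []
        for tc in self.concepts:
            if tc.key not in seen:
                seen.add(tc.key)
                unique.append(tc)
        self.concepts = unique

    def __len__(self) -> int:
        return len(self.concepts)

    def __contains__(self, tc: TermCode) -> bool:
        return any(c == tc for c in self.concepts)

    @property
    def systems(self) -> list[str]:
        out: list[str] = []
        for tc in self.concepts:
            if tc.system not in out:
                out.append(tc.system)
        return out


def _descendant_codes(cs: CodeSystemModel, anchor: str) -> set[str]:
    """Transitive descendants of ``anchor`` within one code system."""
    children: dict[str, list[str]] = {}
    for child, parent in cs.parent_edges:
        children.setdefault(parent, []).append(child)
    out: set[str] = set()
    stack = [anchor]
    while stack:
        code = stack.pop()
        for child in children.get(code, []):
            if child not in out:
                out.add(child)
                stack.append(child)
    return out


def expand_value_set(
    vs: ValueSetModel, registry: Mapping[str, CodeSystemModel]
) -> Expansion:
    """Expand a ValueSet locally against parsed CodeSystems.

    Whole-system rules contribute every concept of the system; explicit
    lists contribute exactly their codes; is-a filter rules contribute the
    anchor plus all transitive descendants.  Rules are unioned and
    de-duplicated on ``(system, code)``.
    """
    concepts: list[TermCode] = []
    for rule in vs.include_rules:
        cs = registry.get(rule.system)
        if cs is None:
            raise MissingCodeSystemError(
                f"ValueSet {vs.url}: code system {rule.system} not in registry"
            )
        if rule.codes is not None:
            codes: Iterable[str] = rule.codes
            for code in codes:
                if code not in cs.concepts:
                    raise UnknownCodeError(
                        f"ValueSet {vs.url}: code {code!r} not in {rule.system}"
                    )
        elif rule.filter_anchor is not None:
            anchor = rule.filter_anchor
            if anchor not in cs.concepts:
                raise UnknownCodeError(
                    f"ValueSet {vs.url}: filter anchor {anchor!r} "
                    f"not in {rule.system}"
                )
            codes = [anchor, *sorted(_descendant_codes(cs, anchor))]
        else:
            codes = list(cs.concepts)
        concepts.extend(cs.term_code(c) for c in codes)
    return Expansion(value_set_url=vs.url, concepts=concepts)


@dataclass
class SubsumptionForest:
    """Is-a hierarchy of an expansion, reduced to essential edges.

    ``child_edges`` maps each parent to its ordered children; ``roots`` are
    the members with no parent inside the expansion.  Edges only ever join
    concepts of the same system.  Sibling order is lexicographic by display
    then code, so serialized output is deterministic.
    """

    nodes: list[TermCode] = field(default_factory=list)
    child_edges: dict[TermCode, list[TermCode]] = field(default_factory=dict)
    roots: list[TermCode] = field(default_factory=list)

    def children_of(self, tc: TermCode) -> list[TermCode]:
        return self.child_edges.get(tc, [])

    def __contains__(self, tc: TermCode) -> bool:
        return tc in set(self.nodes)


def _sort_key(tc: TermCode) -> tuple[str, str]:
    return (tc.display, tc.code)


def build_subsumption_forest(
    exp: Expansion, registry: Mapping[str, CodeSystemModel]
) -> SubsumptionForest:
    """Restrict the registry's is-a closure to the expansion and reduce it."""
    members = {tc.key: tc for tc in exp.concepts}
    closure = nx.DiGraph()
    closure.add_nodes_from(members)
    # ancestor closure per member, walked over the full code system so that
    # chains through non-expanded concepts still connect their endpoints
    for tc in exp.concepts:
        cs = registry.get(tc.system)
        if cs is None:
            raise MissingCodeSystemError(
                f"expansion of {exp.value_set_url}: "
                f"code system {tc.system} not in registry"
            )
        seen: set[str] = set()
        stack = list(cs.parents_of(tc.code))
        while stack:
            code = stack.pop()
            if code in seen:
                continue
            seen.add(code)
            if (tc.system, code) in members:
                closure.add_edge((tc.system, code), tc.key)
            else:
                stack.extend(cs.parents_of(code))
    reduced = nx.transitive_reduction(closure)

    child_edges: dict[TermCode, list[TermCode]] = {}
    for parent_key in reduced.nodes:
        kids = sorted(
            (members[k] for k in reduced.successors(parent_key)), key=_sort_key
        )
        if kids:
            child_edges[members[parent_key]] = kids
    roots = sorted(
        (members[k] for k in reduced.nodes if reduced.in_degree(k) == 0),
        key=_sort_key,
    )
    return SubsumptionForest(
        nodes=list(exp.concepts), child_edges=child_edges, roots=roots
    )


def descendants(forest: SubsumptionForest, tc: TermCode) -> set[TermCode]:
    """All concepts strictly below ``tc`` in the forest."""
    if tc not in forest:
        raise UnknownCodeError(f"{tc.system}|{tc.code} is not in the forest")
    out: set[TermCode] = set()
    stack = list(forest.children_of(tc))
    while stack:
        node = stack.pop()
        if node not in out:
            out.add(node)
            stack.extend(forest.children_of(node))
    out.discard(tc)
    return out


# ---------------------------------------------------------------------------
# remote expansion


def _default_transport(url: str) -> tuple[int, bytes]:
    try:
        with urllib.request.urlopen(url, timeout=30) as resp:  # noqa: S310
            return resp.status, resp.read()
    except urllib.error.HTTPError as exc:
        return exc.code, exc.read()
    except (urllib.error.URLError, OSError) as exc:
        raise TransportError(f"terminology server unreachable: {exc}") from exc


@dataclass
class TerminologyClient:
    """Minimal FHIR terminology-server client for ``ValueSet/$expand``.

    ``transport`` maps a request URL to ``(status, body)``; the default uses
    stdlib HTTP, and tests substitute an in-memory function.  Content served
    from the same artifacts must expand identically to the local path.
    """

    base_url: str
    transport: Callable[[str], tuple[int, bytes]] = _default_transport

    def expand(self, value_set_url: str) -> Expansion:
        query = urllib.parse.urlencode({"url": value_set_url})
        request_url = f"{self.base_url.rstrip('/')}/ValueSet/$expand?{query}"
        status, body = self.transport(request_url)
        try:
            doc = json.loads(body.decode("utf-8"))
        except (UnicodeDecodeError, json.JSONDecodeError) as exc:
            raise ExpansionError(
                f"$expand returned unparseable body for {value_set_url}"
            ) from exc
        if doc.get("resourceType") == "OperationOutcome" or status >= 400:
            issues = "; ".join(
                i.get("diagnostics", i.get("code", "unknown issue"))
                for i in doc.get("issue", [])
            ) or f"HTTP {status}"
            raise ExpansionError(f"$expand failed for {value_set_url}: {issues}")
        contains = doc.get("expansion", {}).get("contains", [])
        concepts = [
            TermCode(
                system=entry["system"],
                code=entry["code"],
                display=entry.get("display", ""),
                version=entry.get("version"),
            )
            for entry in contains
        ]
        return Expansion(value_set_url=value_set_url, concepts=concepts)


def remote_expand(client: TerminologyClient, url: str) -> Expansion:
    """Expand ``url`` through a terminology server (see
    :class:`TerminologyClient` for the contract)."""
    return client.expand(url)
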