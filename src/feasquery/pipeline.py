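"""End-to-end generation: conformance artifacts in, query ontology out.

One call produces the three generated artifacts consumed downstream — the
UI profiles, the criterion mapping, and the terminology tree — plus the
generation report, and can write them to disk in the conventional layout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .artifacts import ArtifactSet, TermCode
from .mapping import (
    CriterionMapping,
    SearchParameterRegistry,
    TermTreeNode,
    generate_mapping,
    generate_term_tree,
)
from .ontology import (
    CategoryTree,
    GenerationReport,
    HandlerSpec,
    TerminologyService,
    category_trees_to_json,
    default_corner_case_registry,
    generate_ui_profiles,
    DEFAULT_DENY_LIST,
)
from .systems import DEFAULT_PREFERENCE

__all__ = ["GenerationResult", "run_generation", "write_outputs"]


@dataclass
class GenerationResult:
    trees: list[CategoryTree]
    report: GenerationReport
    mapping: CriterionMapping
    term_tree: list[TermTreeNode]
    registry: SearchParameterRegistry = field(
        default_factory=SearchParameterRegistry.load_default
    )


def run_generation(
    artifacts: ArtifactSet,
    *,
    preference: Sequence[str] = DEFAULT_PREFERENCE,
    corner_cases: Mapping[str, HandlerSpec] | None = None,
    deny_list: frozenset[str] = DEFAULT_DENY_LIST,
    sp_registry: SearchParameterRegistry | None = None,
    condition_fixed: Mapping[str, tuple[TermCode, ...]] | None = None,
) -> GenerationResult:
    """Generate UI profiles, mapping and terminology tree from one
    artifact set."""
    corner_cases = corner_cases or default_corner_case_registry()
    sp_registry = sp_registry or SearchParameterRegistry.load_default()
    term = TerminologyService(
        value_sets=artifacts.value_sets, code_systems=artifacts.code_systems
    )
    trees, report = generate_ui_profiles(
        artifacts.categories,
        artifacts.profiles,
        term,
        registry=corner_cases,
        preference=preference,
        deny_list=deny_list,
    )
    mapping = generate_mapping(
        trees,
        artifacts.profiles,
        handlers=corner_cases,
        registry=sp_registry,
        condition_fixed=condition_fixed,
    )
    term_tree = generate_term_tree(trees)
    return GenerationResult(
        trees=trees, report=report, mapping=mapping, term_tree=term_tree,
        registry=sp_registry,
    )


def _dump(doc: object, path: Path) -> None:
    path.write_text(
        json.dumps(doc, indent=2, ensure_ascii=False) + "\n", encoding="utf-8"
    )


def write_outputs(result: GenerationResult, out_dir: str | Path) -> None:
    """Write ``ui_profiles.json``, ``mapping.json``,
    ``terminology_tree.json``, the generation report, and the custom
    SearchParameter resources."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _dump(category_trees_to_json(result.trees), out / "ui_profiles.json")
    _dump(result.mapping.to_json(), out / "mapping.json")
    _dump(
        {"roots": [n.to_json() for n in result.term_tree]},
        out / "terminology_tree.json",
    )
    (out / "generation_report.txt").write_text(
        result.report.to_text(), encoding="utf-8"
    )
    sp_dir = out / "custom_search_parameters"
    sp_dir.mkdir(exist_ok=True)
    for resource in result.registry.custom_parameter_resources():
        _dump(resource, sp_dir / f"{resource['name']}.json")
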