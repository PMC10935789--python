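"""Concept layer: node labels, relation categories and permitted edge patterns.

The graph is the labelled directed structure KG = (N, R, A, fN, fR): N are
typed nodes, R the relation categories, A node attributes; fN says which
attributes a label may carry and fR which (label, label, category) triples may
be connected.  The default concept layer — 31 node labels, 9 relation
categories — ships as an editable YAML file and is loaded once per process.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .errors import FormatError

EdgePattern = tuple[str, str, str]  # (source label, target label, category)


@dataclass(frozen=True)
class SchemaConstraint:
    """The permitted labels, categories, edge patterns and attribute sets."""

    labels: frozenset[str]
    categories: frozenset[str]
    edge_patterns: frozenset[EdgePattern]
    label_attributes: dict[str, frozenset[str]] = field(default_factory=dict)

    def allows_label(self, label: str) -> bool:
        return label in self.labels

    def allows_category(self, category: str) -> bool:
        return category in self.categories

    def allows_edge(self, source_label: str, target_label: str, category: str) -> bool:
        return (source_label, target_label, category) in self.edge_patterns

    def allowed_attributes(self, label: str) -> frozenset[str]:
        return self.label_attributes.get(label, frozenset())


def _data_path(filename: str) -> Path:
    return Path(str(resources.files("carekg").joinpath("data", filename)))


def load_schema(path: str | Path | None = None) -> SchemaConstraint:
    """Load a concept-layer file; without ``path``, the packaged default."""
    path = _data_path("schema.yaml") if path is None else Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    for key in ("labels", "categories", "edge_patterns"):
        if key not in raw:
            raise FormatError(f"schema file {path} is missing section {key!r}")
    patterns = set()
    for row in raw["edge_patterns"]:
        if len(row) != 3:
            raise FormatError(f"edge pattern {row!r} must be [source, target, category]")
        patterns.add(tuple(row))
    return SchemaConstraint(
        labels=frozenset(raw["labels"]),
        categories=frozenset(raw["categories"]),
        edge_patterns=frozenset(patterns),
        label_attributes={
            label: frozenset(attrs)
            for label, attrs in (raw.get("label_attributes") or {}).items()
        },
    )


def default_schema() -> SchemaConstraint:
    return load_schema(None)
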