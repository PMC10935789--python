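"""Template-based question answering over the care knowledge graph.

Pipeline: feature dictionary (all node names + aliases) → domain tree
(question-class taxonomy with trigger phrases) → deterministic longest-match
entity recognition → question classification → graph-query construction →
templated natural-language answer.  The emitted query string uses the Cypher
dialect so plans stay portable to a graph database, while execution runs
against the in-memory graph's undirected triple matcher.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import FormatError, InputError
from .graph import KnowledgeGraph, canonical_name
from .schema import _data_path

# Cypher label/relationship dialect tables (bidirectional)
_CYPHER_LABEL = {"disease": "Disease", "medication": "Medication",
                 "diet": "Diet", "symptom": "Symptom",
                 "examination": "Examination"}
_LABEL_FROM_CYPHER = {v: k for k, v in _CYPHER_LABEL.items()}
_CYPHER_REL = {"treatment": "TREATS", "prevention": "PREVENTS",
               "initiation": "INITIATION", "diagnosis": "DIAGNOSIS",
               "examination": "EXAMINATION", "complication": "COMPLICATION",
               "diet_information": "DIET_INFORMATION",
               "basic_information": "BASIC_INFORMATION",
               "physical_information": "PHYSICAL_INFORMATION"}
_REL_FROM_CYPHER = {v: k for k, v in _CYPHER_REL.items()}

_QUERY_RE = re.compile(
    r"^MATCH p = \(m:(\w+)\)-\[r:([\w|]+)\]-\(n(?::(\w+))?\) "
    r"where m\.name = '(.*)' return p$")

FALLBACK_ANSWER = ("Sorry, I could not understand the question or find "
                   "related knowledge.")


@dataclass
class FeatureDictionary:
    """surface form (canonical text) → (node label, canonical name)."""

    entries: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)

    def lookup(self, surface: str) -> tuple[str, str] | None:
        return self.entries.get(canonical_name(surface))


@dataclass
class DomainLeaf:
    id: str
    triggers: list[str]
    entity_label: str
    pattern: dict
    cypher: dict
    answer: str


@dataclass
class DomainTree:
    leaves: list[DomainLeaf]

    def __iter__(self):
        return iter(self.leaves)


@dataclass
class QuestionPlan:
    question: str
    entities: list[tuple[str, str, str]]  # (surface, label, canonical name)
    question_class: str | None = None
    query: dict | None = None             # pattern for match_triples
    query_string: str | None = None       # emitted Cypher text
    answer_template: str | None = None

    @property
    def answerable(self) -> bool:
        return self.question_class is not None


def load_aliases(path: str | Path | None = None) -> dict[str, tuple[str, str]]:
    path = _data_path("aliases.yaml") if path is None else Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return {surface: (label, name)
            for surface, (label, name) in (raw.get("aliases") or {}).items()}


def load_domain_tree(path: str | Path | None = None) -> DomainTree:
    path = _data_path("domain_tree.yaml") if path is None else Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    leaves = [DomainLeaf(**leaf) for leaf in raw["leaves"]]
    for leaf in leaves:
        if not leaf.triggers:
            raise FormatError(f"domain leaf {leaf.id!r} has no trigger phrases")
    return DomainTree(leaves)


def build_dictionary(
    graph: KnowledgeGraph,
    aliases: dict[str, tuple[str, str]] | None = None,
) -> FeatureDictionary:
    """One entry per graph node name plus one per alias; an alias colliding
    with a different canonical target is a format error."""
    entries: dict[str, tuple[str, str]] = {}
    for node in graph.nodes():  # sorted: deterministic collision resolution
        entries.setdefault(node.key, (node.label, node.name))
    for surface, (label, name) in sorted((aliases or {}).items()):
        if not surface.strip():
            raise FormatError("alias surface form must be non-empty")
        key = canonical_name(surface)
        target = (label, name)
        if key in entries and (entries[key][0] != label
                               or canonical_name(entries[key][1])
                               != canonical_name(name)):
            raise FormatError(f"alias {surface!r} collides with existing entry "
                              f"{entries[key]}")
        entries[key] = target
    return FeatureDictionary(entries)


def _find_entities(question: str,
                   dictionary: FeatureDictionary) -> list[tuple[str, str, str]]:
    """Deterministic longest-match scan; matched spans are masked so shorter
    surfaces cannot re-match inside a longer one."""
    text = canonical_name(question)
    taken = [False] * len(text)
    found: list[tuple[int, str, str, str]] = []
    for surface in sorted(dictionary.entries,
                          key=lambda s: (-len(s), s)):
        for m in re.finditer(rf"(?<![\w']){re.escape(surface)}(?![\w'])", text):
            if any(taken[m.start():m.end()]):
                continue
            for i in range(m.start(), m.end()):
                taken[i] = True
            label, name = dictionary.entries[surface]
            found.append((m.start(), surface, label, name))
    found.sort()
    return [(s, l, n) for _, s, l, n in found]


def classify_question(
    question: str,
    dictionary: FeatureDictionary,
    tree: DomainTree,
) -> QuestionPlan:
    """Entities by longest match; class = first leaf (priority order) whose
    triggers fire and whose required entity label is present.  A question
    with no entities or no matching leaf yields an unanswerable plan, not an
    exception."""
    if not question.strip():
        raise InputError("question must be non-empty")
    plan = QuestionPlan(question=question,
                        entities=_find_entities(question, dictionary))
    if not plan.entities:
        return plan
    text = canonical_name(question)
    labels_present = {label for _, label, _ in plan.entities}
    for leaf in tree:
        if leaf.entity_label not in labels_present:
            continue
        if any(re.search(rf"\b{re.escape(t)}\b", text) for t in leaf.triggers):
            plan.question_class = leaf.id
            plan.answer_template = leaf.answer
            plan.query = dict(leaf.pattern)
            break
    return plan


def build_query(plan: QuestionPlan, tree: DomainTree) -> QuestionPlan:
    """Instantiate the class template with the entity's canonical name and
    emit the Cypher-dialect query string."""
    if plan.question_class is None:
        raise InputError("plan has no question class")
    leaf = next(l for l in tree if l.id == plan.question_class)
    entity = next((name for _, label, name in plan.entities
                   if label == leaf.entity_label), None)
    if entity is None:
        raise InputError(f"no entity of label {leaf.entity_label!r} in plan")
    plan.query = dict(leaf.pattern, source_name=canonical_name(entity))
    rels = "|".join(leaf.cypher["rels"])
    target = leaf.cypher.get("target")
    n_part = f"(n:{target})" if target else "(n)"
    plan.query_string = (
        f"MATCH p = (m:{leaf.cypher['source']})-[r:{rels}]-{n_part} "
        f"where m.name = '{canonical_name(entity)}' return p")
    return plan


def parse_query(query_string: str) -> dict:
    """Parse an emitted query string back into a match_triples pattern."""
    m = _QUERY_RE.match(query_string)
    if m is None:
        raise FormatError(f"unparseable query string: {query_string!r}")
    src, rels, tgt, name = m.groups()
    return {
        "source_label": _LABEL_FROM_CYPHER[src],
        "categories": [_REL_FROM_CYPHER[r] for r in rels.split("|")],
        "target_label": _LABEL_FROM_CYPHER[tgt] if tgt else None,
        "source_name": name,
    }


@dataclass
class Answer:
    question: str
    plan: QuestionPlan
    results: list[str]  # entity names, lexicographic
    sentence: str

    @property
    def answerable(self) -> bool:
        return self.plan.answerable


def execute_plan(graph: KnowledgeGraph, plan: QuestionPlan) -> list[str]:
    assert plan.query is not None
    results: set[str] = set()
    for category in plan.query["categories"]:
        for _, _, other in graph.match_triples(
            source_label=plan.query["source_label"],
            category=category,
            target_label=plan.query["target_label"],
            source_name=plan.query["source_name"],
        ):
            results.add(other.name)
    return sorted(results, key=canonical_name)


def answer_question(
    graph: KnowledgeGraph,
    question: str,
    dictionary: FeatureDictionary | None = None,
    tree: DomainTree | None = None,
) -> Answer:
    """End-to-end QA: dictionary → classification → query → templated answer.

    Unanswerable questions (no recognised entity, no matching class, or an
    empty result set) receive a fixed fallback sentence.
    """
    tree = tree or load_domain_tree()
    dictionary = dictionary or build_dictionary(graph, load_aliases())
    plan = classify_question(question, dictionary, tree)
    if not plan.answerable:
        return Answer(question, plan, [], FALLBACK_ANSWER)
    plan = build_query(plan, tree)
    results = execute_plan(graph, plan)
    if not results:
        return Answer(question, plan, [], FALLBACK_ANSWER)
    leaf_entity = next(name for _, label, name in plan.entities
                       if canonical_name(name) == plan.query["source_name"])
    sentence = plan.answer_template.format(entity=leaf_entity,
                                           items=", ".join(results))
    return Answer(question, plan, results, sentence)
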