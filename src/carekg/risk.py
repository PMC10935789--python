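"""Rule-based risk identification over the care knowledge graph.

Three risk categories are screened for each elder:

* **registration risk** — inconsistencies in what was registered, e.g. a
  medication whose treated disease is missing from the elder's record.  The
  logic is the truth table fR1 ∧ fR2 ∧ ¬fR3: the elder is linked to a drug
  (fR1), the drug treats a disease in the curated knowledge (fR2), but the
  elder has no link to that disease (fR3 false) → warn.
* **care risk** — diseases reachable from the elder through short paths
  (two or three hops) via lifestyle and body-state nodes (diet, sleep,
  psychology, exercise, physical indices/conditions), ending in an
  aetiology-type edge.
* **medical risk** — sensor categories at or above a configured severity
  (e.g. blood pressure at the 140/90 second degree materialises a
  provisional hypertension diagnosis edge), drug–drug interaction pairs,
  and diet–drug interaction pairs.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import NotFoundError
from .graph import Edge, KnowledgeGraph, Node, Path as GraphPath, canonical_name
from .ingest import current_category
from .schema import _data_path
from .transform import SensorThresholds, default_thresholds

#: labels that may appear between the elder and a disease in a care-risk path
LIFESTYLE_LABELS = frozenset({
    "diet", "sleep", "psychology", "psychological_factor", "sport",
    "physical_index", "physical_condition",
})

#: edge categories that make the final hop of a care-risk path
AETIOLOGY_CATEGORIES = frozenset({"initiation", "prevention", "complication"})


@dataclass
class RiskRule:
    id: str
    kind: str  # registration | medical_threshold | interaction
    hops: list[dict] = field(default_factory=list)
    absent_categories: list[str] = field(default_factory=list)
    severity: str = "warning"
    message: str = ""


@dataclass
class RiskFinding:
    elder: str
    category: str  # registration | care | medical
    rule_id: str
    evidence: list[Edge]
    message: str
    severity: str  # info | warning | critical

    def sort_key(self):
        return (self.category, self.rule_id, self.message)


def load_rules(path: str | Path | None = None) -> list[RiskRule]:
    path = _data_path("rules.yaml") if path is None else Path(path)
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    return [RiskRule(**r) for r in raw.get("rules", [])]


def _load_pairs(path: Path) -> list[tuple[str, str]]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        next(reader, None)  # header
        return [(canonical_name(a), canonical_name(b))
                for a, b, *_ in reader if a and b]


def load_drug_interactions(path: str | Path | None = None) -> list[tuple[str, str]]:
    return _load_pairs(_data_path("drug_drug_interactions.csv")
                       if path is None else Path(path))


def load_diet_interactions(path: str | Path | None = None) -> list[tuple[str, str]]:
    return _load_pairs(_data_path("diet_drug_interactions.csv")
                       if path is None else Path(path))


def _elder(graph: KnowledgeGraph, elder: str) -> Node:
    node = graph.find_node("name", elder)
    if node is None:
        raise NotFoundError(f"unknown elder {elder!r}")
    return node


def _edge_between(graph: KnowledgeGraph, a: str, b: str,
                  categories: list[str]) -> Edge | None:
    for cat in categories:
        if graph.has_edge(a, b, cat) or graph.has_edge(b, a, cat):
            return next(e for e in graph.edges_touching(a)
                        if e.category == cat and {e.source, e.target} == {a, b})
    return None


# --------------------------------------------------------------------------
# Registration risk
# --------------------------------------------------------------------------

def check_registration_risk(
    graph: KnowledgeGraph, elder: str,
    rules: list[RiskRule] | None = None,
) -> list[RiskFinding]:
    """Findings for every rule chain that holds while the closing edge is
    absent; deduplicated per (via-node, end-node)."""
    elder_node = _elder(graph, elder)
    rules = rules if rules is not None else load_rules()
    findings: list[RiskFinding] = []
    for rule in rules:
        if rule.kind != "registration" or len(rule.hops) != 2:
            continue
        hop1, hop2 = rule.hops
        seen: set[tuple[str, str]] = set()
        for via in graph.neighbors_by_category(elder_node.id, hop1["category"],
                                               hop1["label"]):
            for end in graph.neighbors_by_category(via.id, hop2["category"],
                                                   hop2["label"]):
                if (via.id, end.id) in seen:
                    continue
                seen.add((via.id, end.id))
                if _edge_between(graph, elder_node.id, end.id,
                                 rule.absent_categories) is not None:
                    continue  # fR3 holds — consistent
                e1 = _edge_between(graph, elder_node.id, via.id, [hop1["category"]])
                e2 = _edge_between(graph, via.id, end.id, [hop2["category"]])
                findings.append(RiskFinding(
                    elder=elder_node.name,
                    category="registration",
                    rule_id=rule.id,
                    evidence=[e for e in (e1, e2) if e is not None],
                    message=rule.message.format(elder=elder_node.name,
                                                via=via.name, end=end.name),
                    severity=rule.severity,
                ))
    findings.sort(key=RiskFinding.sort_key)
    return findings


# --------------------------------------------------------------------------
# Care risk
# --------------------------------------------------------------------------

def _is_care_path(graph: KnowledgeGraph, path: GraphPath) -> bool:
    if len(path.edges) < 2:
        return False
    for nid in path.nodes[1:-1]:
        if graph.get_node(nid).label not in LIFESTYLE_LABELS:
            return False
    return path.edges[-1].category in AETIOLOGY_CATEGORIES


def find_care_risks(
    graph: KnowledgeGraph, elder: str, max_depth: int = 3
) -> list[RiskFinding]:
    """One finding per simple path elder →(lifestyle nodes)→ disease of
    length ≤ ``max_depth``, ordered deterministically; the path is the
    evidence."""
    if not 2 <= max_depth <= 3:
        raise ValueError("max_depth must be 2 or 3")
    elder_node = _elder(graph, elder)
    findings = []
    for path in graph.find_paths(elder_node.id, "disease", max_depth,
                                 direction="undirected"):
        if not _is_care_path(graph, path):
            continue
        disease = graph.get_node(path.nodes[-1])
        via = " -> ".join(graph.get_node(n).name for n in path.nodes[1:-1])
        findings.append(RiskFinding(
            elder=elder_node.name,
            category="care",
            rule_id="lifestyle-path",
            evidence=list(path.edges),
            message=(f"{elder_node.name} may be at risk of {disease.name} "
                     f"via {via} ({path.edges[-1].category})."),
            severity="info",
        ))
    findings.sort(key=RiskFinding.sort_key)
    return findings


# --------------------------------------------------------------------------
# Medical risk
# --------------------------------------------------------------------------

def find_medical_risks(
    graph: KnowledgeGraph, elder: str,
    thresholds: SensorThresholds | None = None,
    drug_pairs: list[tuple[str, str]] | None = None,
    diet_pairs: list[tuple[str, str]] | None = None,
) -> list[RiskFinding]:
    """Sensor-threshold findings (materialising provisional diagnosis
    edges), drug–drug interaction findings and diet–drug interaction
    findings for one elder."""
    thresholds = thresholds or default_thresholds()
    drug_pairs = load_drug_interactions() if drug_pairs is None else drug_pairs
    diet_pairs = load_diet_interactions() if diet_pairs is None else diet_pairs
    elder_node = _elder(graph, elder)
    findings: list[RiskFinding] = []

    # (a) sensor categories at or above the configured severity
    for family in ("blood_pressure", "glucose", "bmi", "mattress"):
        node = current_category(graph, elder, family, thresholds)
        if node is None:
            continue
        rule = thresholds.risk_rule(family)
        degree = int(node.attributes.get("degree", 0))
        if rule and degree >= rule["min_degree"]:
            disease_id = graph.add_node("disease", rule["disease"])
            e1 = graph.add_edge(node.id, disease_id, "diagnosis",
                                {"provenance": "sensor-risk"})
            e2 = graph.add_edge(elder_node.id, disease_id, "diagnosis",
                                {"provenance": "sensor-risk"})
            link = _edge_between(graph, elder_node.id, node.id,
                                 ["physical_information"])
            findings.append(RiskFinding(
                elder=elder_node.name,
                category="medical",
                rule_id=f"sensor-threshold-{family}",
                evidence=[e for e in (link, e1, e2) if e is not None],
                message=(f"{elder_node.name}'s current {family.replace('_', ' ')} "
                         f"category is '{node.name}' (degree {degree}); "
                         f"possible {rule['disease']} — provisional diagnosis "
                         "recorded."),
                severity="critical" if degree >= 2 else "warning",
            ))
        elif degree > 0 or node.key == "low blood glucose":
            link = _edge_between(graph, elder_node.id, node.id,
                                 ["physical_information"])
            findings.append(RiskFinding(
                elder=elder_node.name,
                category="medical",
                rule_id=f"sensor-flag-{family}",
                evidence=[link] if link else [],
                message=(f"{elder_node.name}'s current {family.replace('_', ' ')} "
                         f"category is '{node.name}'; continued monitoring "
                         "advised."),
                severity="info",
            ))

    # (b) drug–drug interactions
    meds = graph.neighbors_by_category(elder_node.id, "basic_information",
                                       "medication")
    med_keys = {m.key: m for m in meds}
    for a, b in drug_pairs:
        if a in med_keys and b in med_keys:
            e1 = _edge_between(graph, elder_node.id, med_keys[a].id,
                               ["basic_information"])
            e2 = _edge_between(graph, elder_node.id, med_keys[b].id,
                               ["basic_information"])
            findings.append(RiskFinding(
                elder=elder_node.name,
                category="medical",
                rule_id="drug-drug-interaction",
                evidence=[e for e in (e1, e2) if e is not None],
                message=(f"{med_keys[a].name} and {med_keys[b].name} may "
                         "interact; review the medication plan."),
                severity="warning",
            ))

    # (c) diet–drug interactions
    diets = graph.neighbors_by_category(elder_node.id, "diet_information", "diet")
    diet_keys = {d.key: d for d in diets}
    for food, drug in diet_pairs:
        if food in diet_keys and drug in med_keys:
            e1 = _edge_between(graph, elder_node.id, diet_keys[food].id,
                               ["diet_information"])
            e2 = _edge_between(graph, elder_node.id, med_keys[drug].id,
                               ["basic_information"])
            findings.append(RiskFinding(
                elder=elder_node.name,
                category="medical",
                rule_id="diet-drug-interaction",
                evidence=[e for e in (e1, e2) if e is not None],
                message=(f"{diet_keys[food].name} may interact with "
                         f"{med_keys[drug].name}; adjust the diet."),
                severity="warning",
            ))

    findings.sort(key=RiskFinding.sort_key)
    return findings


def all_risks(graph: KnowledgeGraph, elder: str,
              thresholds: SensorThresholds | None = None) -> list[RiskFinding]:
    return (check_registration_risk(graph, elder)
            + find_care_risks(graph, elder)
            + find_medical_risks(graph, elder, thresholds))
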