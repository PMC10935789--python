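"""Personalised care-guideline report generation.

A report always has exactly three chapters — basic information, health
information, diet information — and each chapter exactly two subsections,
risk identification and care recommendations, regardless of how sparse the
elder's data is.  Profiles are populated by fixed retrieval patterns over
the elder's neighbourhood; risks come from the risk engine partitioned by
scope; recommendations are templated sentences bound to prevention and
examination edges in the curated knowledge.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

from .errors import InputError, NotFoundError
from .graph import Edge, KnowledgeGraph, canonical_name
from .ingest import current_category
from .risk import (RiskFinding, check_registration_risk, find_care_risks,
                   find_medical_risks)
from .schema import _data_path
from .transform import SensorThresholds, default_thresholds

CHAPTERS = ("basic_information", "health_information", "diet_information")

CHAPTER_TITLES = {
    "basic_information": "Basic information",
    "health_information": "Health information",
    "diet_information": "Diet information",
}

#: which labels each chapter's profile retrieves, via which edge categories
_PROFILE_PATTERNS = {
    "basic_information": [
        ("basic_information", ("sex", "age", "type", "marriage", "spouse",
                               "child", "child_type", "caregiver", "income",
                               "expenditure", "subsidy", "hobby", "social",
                               "living_environment", "smart_phone",
                               "smart_device", "disease",
                               "direct_chronic_history",
                               "collateral_chronic_history", "examination")),
    ],
    "health_information": [
        ("basic_information", ("medication",)),
        ("physical_information", ("sleep", "sport", "psychology",
                                  "psychological_factor", "physical_condition",
                                  "physical_index", "symptom", "excretion")),
        ("diagnosis", ("disease",)),
    ],
    "diet_information": [
        ("diet_information", ("diet",)),
    ],
}

#: diseases whose monitoring relies on a sensor family
_MONITORING = {"hypertension": ("blood_pressure", "blood pressure"),
               "diabetes": ("glucose", "fasting blood glucose")}


@dataclass
class Chapter:
    profile: dict[str, list[str]] = field(default_factory=dict)
    risks: list[RiskFinding] = field(default_factory=list)
    recommendations: list[str] = field(default_factory=list)


@dataclass
class CareReport:
    elder: str
    chapters: dict[str, Chapter]
    generated_at: str

    def to_dict(self) -> dict:
        return {
            "elder": self.elder,
            "generated_at": self.generated_at,
            "chapters": {
                key: {
                    "profile": ch.profile,
                    "risks": [
                        {"elder": f.elder, "category": f.category,
                         "rule_id": f.rule_id, "message": f.message,
                         "severity": f.severity,
                         "evidence": [[e.source, e.target, e.category]
                                      for e in f.evidence]}
                        for f in ch.risks
                    ],
                    "recommendations": ch.recommendations,
                }
                for key, ch in self.chapters.items()
            },
        }

    @classmethod
    def from_dict(cls, raw: dict) -> "CareReport":
        chapters = {}
        for key, ch in raw["chapters"].items():
            chapters[key] = Chapter(
                profile={k: list(v) for k, v in ch["profile"].items()},
                risks=[RiskFinding(
                    elder=f["elder"], category=f["category"],
                    rule_id=f["rule_id"], message=f["message"],
                    severity=f["severity"],
                    evidence=[Edge(s, t, c) for s, t, c in f["evidence"]],
                ) for f in ch["risks"]],
                recommendations=list(ch["recommendations"]),
            )
        return cls(raw["elder"], chapters, raw["generated_at"])


def _load_templates() -> dict[str, str]:
    with open(_data_path("report_templates.yaml"), encoding="utf-8") as fh:
        return yaml.safe_load(fh)


def _chapter_of(finding: RiskFinding, graph: KnowledgeGraph) -> str:
    """Scope partition: registration → ch.1; diet-related → ch.3; rest → ch.2."""
    if finding.category == "registration":
        return "basic_information"
    if finding.rule_id == "diet-drug-interaction":
        return "diet_information"
    if finding.category == "care" and finding.evidence:
        first = finding.evidence[0]
        for nid in (first.source, first.target):
            if graph.has_node(nid) and graph.get_node(nid).label == "diet":
                return "diet_information"
    return "health_information"


def _finding_diseases(finding: RiskFinding, graph: KnowledgeGraph) -> set[str]:
    out = set()
    for edge in finding.evidence:
        for nid in (edge.source, edge.target):
            if graph.has_node(nid):
                node = graph.get_node(nid)
                if node.label == "disease":
                    out.add(node.key)
    return out


def build_report(
    graph: KnowledgeGraph,
    elder: str,
    thresholds: SensorThresholds | None = None,
) -> CareReport:
    """Retrieve, screen and summarise one elder into a three-chapter report."""
    thresholds = thresholds or default_thresholds()
    elder_node = graph.find_node("name", elder)
    if elder_node is None:
        raise NotFoundError(f"unknown elder {elder!r}")
    templates = _load_templates()
    chapters = {key: Chapter() for key in CHAPTERS}

    # profiles by fixed retrieval patterns
    for chapter, patterns in _PROFILE_PATTERNS.items():
        profile: dict[str, list[str]] = {}
        for category, labels in patterns:
            for edge in graph.edges_touching(elder_node.id):
                if edge.category != category:
                    continue
                other = graph.get_node(
                    edge.target if edge.source == elder_node.id else edge.source)
                if other.label in labels:
                    profile.setdefault(other.label, [])
                    if other.name not in profile[other.label]:
                        profile[other.label].append(other.name)
        chapters[chapter].profile = {k: sorted(v) for k, v in sorted(profile.items())}

    # risk subsections, partitioned by scope
    findings = (check_registration_risk(graph, elder)
                + find_care_risks(graph, elder)
                + find_medical_risks(graph, elder, thresholds))
    for finding in findings:
        chapters[_chapter_of(finding, graph)].risks.append(finding)

    # recommendation subsections
    registered = {n.key: n for n in
                  graph.neighbors_by_category(elder_node.id, "basic_information",
                                              "disease")}
    registered.update({n.key: n for n in
                       graph.neighbors_by_category(elder_node.id, "diagnosis",
                                                   "disease")})
    at_risk = dict(registered)
    for finding in findings:
        for key in _finding_diseases(finding, graph):
            node = graph.nodes("disease")
            at_risk.setdefault(key, next(n for n in node if n.key == key))

    for key in sorted(at_risk):
        disease = at_risk[key]
        diet_items, habit_items, exams = [], [], []
        for edge in graph.edges_touching(disease.id):
            other = graph.get_node(
                edge.target if edge.source == disease.id else edge.source)
            if edge.category == "prevention":
                (diet_items if other.label == "diet" else habit_items).append(
                    other.name)
            elif edge.category == "examination" and other.label == "examination":
                exams.append(other.name)
        if diet_items:
            chapters["diet_information"].recommendations.append(
                templates["prevention_diet"].format(
                    disease=disease.name, items=", ".join(sorted(diet_items))))
        if habit_items:
            chapters["health_information"].recommendations.append(
                templates["prevention_habit"].format(
                    disease=disease.name, items=", ".join(sorted(habit_items))))
        if exams:
            chapters["health_information"].recommendations.append(
                templates["examination"].format(
                    disease=disease.name, items=", ".join(sorted(exams))))
        monitoring = _MONITORING.get(disease.key)
        if monitoring and current_category(graph, elder, monitoring[0],
                                           thresholds) is None:
            chapters["health_information"].recommendations.append(
                templates["measurement"].format(measure=monitoring[1],
                                                disease=disease.name))
        if disease.key == canonical_name("Alzheimer's disease"):
            chapters["basic_information"].recommendations.append(
                templates["caveat"].format(disease=disease.name))

    for ch in chapters.values():
        ch.recommendations = sorted(set(ch.recommendations))

    return CareReport(
        elder=elder_node.name,
        chapters=chapters,
        generated_at=datetime.now(timezone.utc).strftime("%Y-%m-%dT%H:%M:%SZ"),
    )


def render_report(report: CareReport, format: str = "markdown") -> str:
    """Deterministic rendering to Markdown or JSON."""
    if format == "json":
        return json.dumps(report.to_dict(), indent=2, sort_keys=True,
                          ensure_ascii=False)
    if format != "markdown":
        raise InputError(f"unknown report format {format!r}")

    lines = [f"# Care report: {report.elder}", "",
             f"Generated at {report.generated_at}", ""]
    for key in CHAPTERS:
        ch = report.chapters[key]
        lines.append(f"## {CHAPTER_TITLES[key]}")
        lines.append("")
        if ch.profile:
            for label, names in ch.profile.items():
                lines.append(f"- {label.replace('_', ' ')}: {', '.join(names)}")
            lines.append("")
        lines.append("### Risk identification")
        lines.append("")
        if ch.risks:
            for f in ch.risks:
                lines.append(f"- [{f.severity}] {f.message}")
        else:
            lines.append("- No risks identified.")
        lines.append("")
        lines.append("### Care recommendations")
        lines.append("")
        if ch.recommendations:
            lines.extend(f"- {r}" for r in ch.recommendations)
        else:
            lines.append("- No specific recommendations.")
        lines.append("")
    return "\n".join(lines)


def parse_report(document: str) -> CareReport:
    """Inverse of ``render_report(..., format='json')``."""
    return CareReport.from_dict(json.loads(document))
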