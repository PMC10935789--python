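"""Loading data into the graph and applying dynamic sensor updates.

Three sources feed the care graph:

* curated medical/nursing knowledge as bulk-import CSV node/edge files
  (``id:ID,name,:LABEL,attr...`` / ``:START_ID,:END_ID,:TYPE``);
* per-elder care questionnaires (JSON records answering the shipped
  template of 100+ questions, each mapped declaratively to a node label and
  relation category);
* smart-sensor readings (JSON Lines), which are classified by
  :mod:`carekg.transform` and *rewire* the elder's single category edge per
  sensor family — e.g. from "normal blood pressure" to "2nd degree
  hypertension" — while the raw reading is appended to an elder-level log
  kept outside the graph.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Any, Iterable

from .errors import FormatError, NotFoundError, SchemaViolationError
from .graph import Edge, KnowledgeGraph, Node, Scalar, canonical_name
from .transform import CategoryResult, SensorThresholds, default_thresholds

# --------------------------------------------------------------------------
# Questionnaire template
#
# Each row: (question_key, node_label, relation_category, kind, fixed_name)
#   kind "value": the answer string becomes the node name
#   kind "flag":  a truthy answer links the elder to the fixed node name
#   kind "list":  each list element becomes a node
#   kind "attr":  the answer is stored as an attribute on the elder node
# --------------------------------------------------------------------------

_B, _P, _D = "basic_information", "physical_information", "diet_information"


def _rows() -> list[tuple[str, str, str, str, str | None]]:
    rows: list[tuple[str, str, str, str, str | None]] = []

    def value(key, label, cat):
        rows.append((key, label, cat, "value", None))

    def flag(key, label, cat, name):
        rows.append((key, label, cat, "flag", name))

    def lst(key, label, cat):
        rows.append((key, label, cat, "list", None))

    def attr(key):
        rows.append((key, "name", _B, "attr", None))

    # -- chapter 1: basic information -------------------------------------
    value("sex", "sex", _B)
    value("age", "age", _B)
    value("elder_type", "type", _B)
    value("subsidy_type", "subsidy", _B)
    value("subsidy_amount", "subsidy", _B)
    value("monthly_income", "income", _B)
    value("income_source", "income", _B)
    value("monthly_expenditure", "expenditure", _B)
    value("marriage_status", "marriage", _B)
    value("spouse_name", "spouse", _B)
    lst("children", "child", _B)
    value("child_type", "child_type", _B)
    value("caregiver_name", "caregiver", _B)
    value("caregiver_relationship", "caregiver", _B)
    lst("living_environment", "living_environment", _B)
    value("residence_type", "living_environment", _B)
    value("smart_phone_model", "smart_phone", _B)
    value("smartphone_usage", "smart_phone", _B)
    lst("smart_devices", "smart_device", _B)
    for h in ("reading", "gardening", "television", "chess", "music",
              "calligraphy", "fishing", "dancing"):
        flag(f"hobby_{h}", "hobby", _B, h)
    flag("social_community_events", "social", _B, "community events")
    flag("social_senior_center", "social", _B, "senior center")
    flag("social_volunteering", "social", _B, "volunteering")
    flag("social_religious_activities", "social", _B, "religious activities")
    value("social_contact_frequency", "social", _B)
    lst("past_diseases", "disease", _B)
    lst("current_medications", "medication", _B)
    lst("direct_chronic_history", "direct_chronic_history", _B)
    lst("collateral_chronic_history", "collateral_chronic_history", _B)
    lst("recent_examinations", "examination", _B)
    flag("examination_blood_routine_recent", "examination", _B, "blood routine")
    flag("examination_blood_pressure_monitoring", "examination", _B,
         "blood pressure measurement")

    # -- chapter 2: health information ------------------------------------
    value("sleep_quality", "sleep", _P)
    value("sleep_hours", "sleep", _P)
    value("sleep_bedtime", "sleep", _P)
    flag("sleep_insomnia", "sleep", _P, "insomnia")
    flag("sleep_snoring", "sleep", _P, "snoring")
    flag("sleep_daytime_naps", "sleep", _P, "daytime naps")
    for s in ("walking", "taichi", "square_dancing", "swimming", "cycling"):
        flag(f"sport_{s}", "sport", _P, s.replace("_", " "))
    value("sport_frequency", "sport", _P)
    value("sport_duration_minutes", "sport", _P)
    value("psychology_mood", "psychology", _P)
    value("psychology_life_satisfaction", "psychology", _P)
    flag("psychology_loneliness", "psychology", _P, "loneliness")
    flag("psychology_anxiety", "psychology", _P, "anxiety")
    flag("psychology_low_mood", "psychology", _P, "low mood")
    flag("factor_bereavement", "psychological_factor", _P, "bereavement")
    flag("factor_family_conflict", "psychological_factor", _P, "family conflict")
    flag("factor_financial_stress", "psychological_factor", _P, "financial stress")
    for c in ("constipation", "vision_impaired", "hearing_impaired",
              "mobility_limited", "falls_last_year", "chewing_difficulty",
              "chronic_pain", "teeth_missing"):
        flag(f"condition_{c}", "physical_condition", _P, c.replace("_", " "))
    flag("habit_smoking", "physical_condition", _P, "smoking")
    value("excretion_pattern", "excretion", _P)
    flag("excretion_incontinence", "excretion", _P, "incontinence")
    for s in ("chest_tightness", "palpitations", "fatigue", "headache",
              "vomiting", "dizziness", "shortness_of_breath", "blurred_vision",
              "numbness", "edema"):
        flag(f"symptom_{s}", "symptom", _P, s.replace("_", " "))
    attr("height_m")
    attr("weight_kg")
    flag("index_overweight", "physical_index", _P, "overweight")
    flag("index_underweight", "physical_index", _P, "underweight")

    # -- chapter 3: diet information --------------------------------------
    for d, name in (
        ("high_salt", "high salt diet"), ("high_oil", "high oil diet"),
        ("vegetables_daily", "daily vegetables"), ("fruit_daily", "daily fruit"),
        ("red_meat_often", "frequent red meat"), ("fish_weekly", "weekly fish"),
        ("sugary_drinks", "sugary drinks"), ("pickled_food", "pickled food"),
        ("fried_food", "fried food"), ("whole_grains", "whole grains"),
        ("dairy_daily", "daily dairy"), ("soy_products", "soy products"),
        ("strong_tea", "strong tea"), ("coffee", "coffee"), ("alcohol", "alcohol"),
    ):
        flag(f"diet_{d}", "diet", _D, name)
    value("diet_meals_per_day", "diet", _D)
    value("diet_appetite", "diet", _D)
    value("diet_preference", "diet", _D)
    lst("diet_supplements", "diet", _D)
    return rows


QUESTIONNAIRE_TEMPLATE: dict[str, tuple[str, str, str, str | None]] = {
    key: (label, cat, kind, fixed) for key, label, cat, kind, fixed in _rows()
}

#: chapter of each question key, by relation category
QUESTION_CHAPTER = {
    key: {"basic_information": "basic_information",
          "physical_information": "health_information",
          "diet_information": "diet_information"}[cat]
    for key, (_, cat, _, _) in QUESTIONNAIRE_TEMPLATE.items()
}


def _answered(value: Any) -> bool:
    if value is None:
        return False
    if isinstance(value, (list, tuple, str)):
        return len(value) > 0
    return bool(value) or isinstance(value, (int, float))


def expected_edge_count(answers: dict[str, Any]) -> int:
    """Edges a record should create under the declarative mapping."""
    n = 0
    for key, value in answers.items():
        if not _answered(value):
            continue
        _, _, kind, _ = QUESTIONNAIRE_TEMPLATE[key]
        if kind == "attr":
            continue
        n += len(value) if kind == "list" else 1
    return n


@dataclass
class QuestionnaireRecord:
    elder_name: str
    answers: dict[str, Any]
    timestamp: str  # ISO date

    @classmethod
    def from_json(cls, path: str | Path) -> "QuestionnaireRecord":
        with open(path, encoding="utf-8") as fh:
            raw = json.load(fh)
        return cls(raw["elder_name"], raw.get("answers", {}),
                   raw.get("timestamp", ""))


@dataclass
class SensorReading:
    elder_name: str
    device: str  # blood_pressure_monitor | glucose_meter | scale | mattress
    timestamp: str  # ISO datetime
    payload: dict[str, Any]

    @classmethod
    def from_json_line(cls, line: str) -> "SensorReading":
        raw = json.loads(line)
        return cls(raw["elder_name"], raw["device"], raw["timestamp"],
                   raw["payload"])


@dataclass
class IngestSummary:
    nodes_added: int = 0
    nodes_merged: int = 0
    edges_added: int = 0
    edges_merged: int = 0
    violations: list[str] = field(default_factory=list)


@dataclass
class UpdateSummary:
    elder: str
    family: str
    result: CategoryResult
    rewired: bool
    previous: str | None  # node name before
    current: str          # node name after


# --------------------------------------------------------------------------
# Bulk-import CSV
# --------------------------------------------------------------------------

def _parse_scalar(text: str) -> Scalar:
    for caster in (int, float):
        try:
            return caster(text)
        except ValueError:
            continue
    return text


def load_kb_triples(
    graph: KnowledgeGraph, nodes_file: str | Path, edges_file: str | Path
) -> IngestSummary:
    """Upsert a bulk-import CSV pair into the graph.

    Schema-violating rows are skipped and reported in the summary, never
    raised, so one bad curated row cannot block an import.
    """
    summary = IngestSummary()
    id_map: dict[str, str] = {}

    with open(nodes_file, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if not header or header[:1] != ["id:ID"] or ":LABEL" not in header:
            raise FormatError(f"{nodes_file}: expected header id:ID,name,:LABEL,...")
        name_i, label_i = header.index("name"), header.index(":LABEL")
        attr_cols = [(i, h) for i, h in enumerate(header)
                     if h not in ("id:ID", "name", ":LABEL")]
        for row in reader:
            if not row:
                continue
            attrs = {h: _parse_scalar(row[i]) for i, h in attr_cols
                     if i < len(row) and row[i] != ""}
            label, name = row[label_i], row[name_i]
            existed = graph.find_node(label, name) is not None
            try:
                nid = graph.add_node(label, name, attrs)
            except SchemaViolationError as exc:
                summary.violations.append(f"node row {row[0]!r}: {exc}")
                continue
            id_map[row[0]] = nid
            summary.nodes_merged += existed
            summary.nodes_added += not existed

    with open(edges_file, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        expected = [":START_ID", ":END_ID", ":TYPE"]
        if not header or header[:3] != expected:
            raise FormatError(f"{edges_file}: expected header :START_ID,:END_ID,:TYPE")
        attr_cols = [(i, h) for i, h in enumerate(header) if i >= 3]
        for row in reader:
            if not row:
                continue
            start, end, category = row[0], row[1], row[2]
            src = id_map.get(start, start if graph.has_node(start) else None)
            tgt = id_map.get(end, end if graph.has_node(end) else None)
            if src is None or tgt is None:
                summary.violations.append(
                    f"edge row {start}->{end}[{category}]: unknown endpoint id")
                continue
            attrs = {h: _parse_scalar(row[i]) for i, h in attr_cols
                     if i < len(row) and row[i] != ""}
            existed = graph.has_edge(src, tgt, category)
            try:
                graph.add_edge(src, tgt, category, attrs)
            except SchemaViolationError as exc:
                summary.violations.append(f"edge row {start}->{end}: {exc}")
                continue
            summary.edges_merged += existed
            summary.edges_added += not existed
    return summary


def export_graph(
    graph: KnowledgeGraph, out_dir: str | Path
) -> tuple[Path, Path]:
    """Write the graph as a bulk-import CSV pair (nodes.csv, edges.csv)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    nodes_file, edges_file = out_dir / "nodes.csv", out_dir / "edges.csv"

    nodes = graph.nodes()
    attr_keys = sorted({k for n in nodes for k in n.attributes})
    with open(nodes_file, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id:ID", "name", ":LABEL", *attr_keys])
        for n in nodes:
            writer.writerow([n.id, n.name, n.label,
                             *[n.attributes.get(k, "") for k in attr_keys]])

    edges = graph.edges()
    eattr_keys = sorted({k for e in edges for k in e.attributes})
    with open(edges_file, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow([":START_ID", ":END_ID", ":TYPE", *eattr_keys])
        for e in edges:
            writer.writerow([e.source, e.target, e.category,
                             *[e.attributes.get(k, "") for k in eattr_keys]])
    return nodes_file, edges_file


# --------------------------------------------------------------------------
# Questionnaires
# --------------------------------------------------------------------------

def load_questionnaire(graph: KnowledgeGraph, record: QuestionnaireRecord) -> str:
    """Map one questionnaire record into the graph; returns the elder node id."""
    if not record.elder_name or not record.elder_name.strip():
        raise FormatError("elder_name must be non-empty")
    unknown = sorted(k for k in record.answers if k not in QUESTIONNAIRE_TEMPLATE)
    if unknown:
        raise FormatError(f"unknown question keys: {', '.join(unknown)}")

    elder = graph.add_node("name", record.elder_name)
    for key in sorted(record.answers):
        value = record.answers[key]
        if not _answered(value):
            continue
        label, category, kind, fixed = QUESTIONNAIRE_TEMPLATE[key]
        if kind == "attr":
            graph.add_node("name", record.elder_name, {key: value})
        elif kind == "flag":
            nid = graph.add_node(label, fixed)
            graph.add_edge(elder, nid, category)
        elif kind == "value":
            nid = graph.add_node(label, str(value))
            graph.add_edge(elder, nid, category)
        elif kind == "list":
            for item in value:
                nid = graph.add_node(label, str(item))
                graph.add_edge(elder, nid, category)
    return elder


# --------------------------------------------------------------------------
# Sensor updates (edge rewiring)
# --------------------------------------------------------------------------

_DEVICE_FAMILY = {
    "blood_pressure_monitor": "blood_pressure",
    "glucose_meter": "glucose",
    "scale": "bmi",
    "mattress": "mattress",
}


def _classify(reading: SensorReading, elder: Node,
              thresholds: SensorThresholds) -> CategoryResult:
    p = reading.payload
    if reading.device == "blood_pressure_monitor":
        return thresholds.classify_blood_pressure(p["sbp"], p["dbp"])
    if reading.device == "glucose_meter":
        return thresholds.classify_glucose(p["glucose"])
    if reading.device == "scale":
        height = p.get("height_m", elder.attributes.get("height_m"))
        if height is None:
            raise FormatError("scale reading needs height_m in payload or on "
                              "the elder record")
        return thresholds.classify_bmi(p["weight_kg"], height)
    if reading.device == "mattress":
        intervals = [(datetime.fromisoformat(a), datetime.fromisoformat(b))
                     for a, b in p["intervals"]]
        return thresholds.summarize_mattress(intervals)
    raise FormatError(f"unknown device {reading.device!r}")


def apply_sensor_reading(
    graph: KnowledgeGraph,
    reading: SensorReading,
    thresholds: SensorThresholds | None = None,
) -> UpdateSummary:
    """Classify a reading and rewire the elder's category edge if it changed.

    Per sensor family the elder keeps exactly one ``physical_information``
    edge to a category node; when a new reading lands in a different
    category, the old edge is removed and an edge to the new category node
    added.  The raw reading is always appended to the elder's reading log.
    """
    thresholds = thresholds or default_thresholds()
    elder_node = graph.find_node("name", reading.elder_name)
    if elder_node is None:
        raise NotFoundError(f"unknown elder {reading.elder_name!r}")
    if reading.device not in _DEVICE_FAMILY:
        raise FormatError(f"unknown device {reading.device!r}")
    family = _DEVICE_FAMILY[reading.device]

    result = _classify(reading, elder_node, thresholds)
    family_names = {canonical_name(n) for n in thresholds.family_node_names(family)}

    previous: str | None = None
    stale: list[Edge] = []
    for edge in graph.edges_touching(elder_node.id):
        if edge.category != "physical_information":
            continue
        other = graph.get_node(
            edge.target if edge.source == elder_node.id else edge.source)
        if other.label == "physical_index" and other.key in family_names:
            previous = other.name
            if other.key != canonical_name(result.node_name):
                stale.append(edge)

    rewired = False
    if previous is None or stale:
        for edge in stale:
            graph.remove_edge(edge.source, edge.target, edge.category)
        cat_id = graph.add_node("physical_index", result.node_name,
                                {"family": family, "degree": result.degree})
        graph.add_edge(elder_node.id, cat_id, "physical_information")
        rewired = previous is not None and bool(stale)

    log = graph.reading_logs.setdefault(elder_node.key, [])
    log.append({"device": reading.device, "timestamp": reading.timestamp,
                "payload": reading.payload, "category": result.category,
                "degree": result.degree, "flags": list(result.flags)})
    return UpdateSummary(elder=reading.elder_name, family=family, result=result,
                         rewired=rewired, previous=previous,
                         current=result.node_name)


def apply_sensor_stream(
    graph: KnowledgeGraph,
    readings: Iterable[SensorReading],
    thresholds: SensorThresholds | None = None,
) -> list[UpdateSummary]:
    return [apply_sensor_reading(graph, r, thresholds) for r in readings]


def current_category(graph: KnowledgeGraph, elder: str, family: str,
                     thresholds: SensorThresholds | None = None) -> Node | None:
    """The category node the elder is currently linked to for a family."""
    thresholds = thresholds or default_thresholds()
    elder_node = graph.find_node("name", elder)
    if elder_node is None:
        raise NotFoundError(f"unknown elder {elder!r}")
    names = {canonical_name(n) for n in thresholds.family_node_names(family)}
    for node in graph.neighbors_by_category(elder_node.id, "physical_information",
                                            "physical_index"):
        if node.key in names:
            return node
    return None
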