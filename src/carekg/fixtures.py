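"""Seeded generators for curated-knowledge CSVs, elder questionnaires and
sensor streams, so the whole system is testable with no external data.

A fixed curated core — the chronic diseases of the worked case (hypertension,
hyperlipidemia, coronary heart disease, diabetes, Alzheimer's disease,
cerebrovascular disease) with their drugs, preventive foods, symptoms and
aetiology links — is embedded verbatim so worked-example behaviour is
seed-independent; synthetic diseases/drugs/foods/symptoms are layered on top
from a single explicit seed.
"""

from __future__ import annotations

import csv
import json
import random
from pathlib import Path
from typing import Any

from pydantic import BaseModel, Field

from .ingest import QUESTIONNAIRE_TEMPLATE, QuestionnaireRecord

# --------------------------------------------------------------------------
# Curated core knowledge (seed-independent)
# --------------------------------------------------------------------------

CORE_DISEASES = ["hypertension", "hyperlipidemia", "coronary heart disease",
                 "diabetes", "alzheimer's disease", "cerebrovascular disease"]

CORE_DRUGS = {  # drug -> treated disease
    "nifedipine": "hypertension",
    "metoprolol": "hypertension",
    "metformin": "diabetes",
    "glibenclamide": "diabetes",
    "atorvastatin": "hyperlipidemia",
    "aspirin": "coronary heart disease",
    "donepezil": "alzheimer's disease",
    "warfarin": "cerebrovascular disease",
}

CORE_FOODS = {  # food -> diseases it helps prevent
    "celery": ["hypertension"],
    "oat": ["hypertension", "hyperlipidemia"],
    "low salt diet": ["hypertension"],
    "low oil diet": ["hyperlipidemia", "coronary heart disease"],
    "whole grains": ["diabetes"],
    "fish": ["coronary heart disease"],
    "grapefruit": [],
}

CORE_SYMPTOMS = {  # disease -> symptoms (diagnosis edges)
    "coronary heart disease": ["vomiting", "chest tightness", "fatigue"],
    "hypertension": ["dizziness", "headache"],
    "diabetes": ["fatigue", "blurred vision"],
    "alzheimer's disease": ["memory loss"],
}

CORE_EXAMS = {  # disease -> examinations
    "hypertension": ["blood pressure measurement"],
    "diabetes": ["fasting blood glucose test"],
    "hyperlipidemia": ["blood lipid panel"],
}

# (label, name, category, disease) aetiology links from the worked case
CORE_AETIOLOGY = [
    ("sleep", "poor sleep quality", "initiation", "hyperlipidemia"),
    ("sleep", "poor sleep quality", "initiation", "coronary heart disease"),
    ("sleep", "insomnia", "initiation", "hypertension"),
    ("physical_index", "overweight", "initiation", "coronary heart disease"),
    ("physical_index", "overweight", "initiation", "hypertension"),
    ("physical_index", "overweight", "initiation", "hyperlipidemia"),
    ("psychology", "low mood", "initiation", "coronary heart disease"),
    ("psychology", "anxiety", "initiation", "hypertension"),
    ("physical_condition", "constipation", "initiation",
     "cerebrovascular disease"),
    ("diet", "high salt diet", "initiation", "hypertension"),
    ("diet", "high oil diet", "initiation", "hyperlipidemia"),
    ("disease", "hyperlipidemia", "initiation", "coronary heart disease"),
    ("disease", "hyperlipidemia", "initiation", "cerebrovascular disease"),
    ("disease", "hypertension", "complication", "coronary heart disease"),
    ("disease", "hypertension", "complication", "cerebrovascular disease"),
    ("sport", "walking", "prevention", "hypertension"),
    ("sport", "taichi", "prevention", "hypertension"),
]


class FixtureSpec(BaseModel):
    """Knobs of the synthetic study population."""

    seed: int = 7
    n_elders: int = Field(default=20, ge=1)  # the trial enrolled 20 elders
    n_diseases: int = Field(default=12, ge=1)
    n_drugs: int = Field(default=20, ge=1)
    n_foods: int = Field(default=15, ge=1)
    n_symptoms: int = Field(default=18, ge=1)
    #: probability of a synthetic aetiology/prevention/symptom link
    edge_density: float = Field(default=0.15, ge=0.0, le=1.0)
    #: probability an elder's medication lacks its disease registration
    fault_rate: float = Field(default=0.25, ge=0.0, le=1.0)
    #: per-device normal distributions for daily readings
    sensor_profile: dict[str, tuple[float, float]] = {
        "sbp": (125.0, 10.0), "dbp": (75.0, 8.0),
        "glucose": (5.5, 0.8), "weight": (62.0, 2.0),
    }


def _rng(spec: FixtureSpec, stream: int) -> random.Random:
    return random.Random(spec.seed * 1_000_003 + stream)


# --------------------------------------------------------------------------
# Knowledge base
# --------------------------------------------------------------------------

def _kb_model(spec: FixtureSpec) -> dict[str, Any]:
    """Deterministic in-memory KB description shared by the CSV writer and
    the questionnaire generator (so profiles stay consistent with the KB)."""
    rng = _rng(spec, 1)
    diseases = list(CORE_DISEASES)
    diseases += [f"synthetic disease {i:02d}"
                 for i in range(max(0, spec.n_diseases - len(diseases)))]
    drugs = dict(CORE_DRUGS)
    for i in range(max(0, spec.n_drugs - len(drugs))):
        drugs[f"synthetic drug {i:02d}"] = rng.choice(diseases)
    foods = {k: list(v) for k, v in CORE_FOODS.items()}
    for i in range(max(0, spec.n_foods - len(foods))):
        linked = [d for d in diseases if rng.random() < spec.edge_density]
        foods[f"synthetic food {i:02d}"] = linked
    symptoms = {k: list(v) for k, v in CORE_SYMPTOMS.items()}
    all_symptoms = sorted({s for ss in symptoms.values() for s in ss})
    extra = max(0, spec.n_symptoms - len(all_symptoms))
    for i in range(extra):
        name = f"synthetic symptom {i:02d}"
        hosts = [d for d in diseases if rng.random() < spec.edge_density]
        for d in hosts or [rng.choice(diseases)]:
            symptoms.setdefault(d, []).append(name)
    return {"diseases": diseases, "drugs": drugs, "foods": foods,
            "symptoms": symptoms, "exams": dict(CORE_EXAMS),
            "aetiology": list(CORE_AETIOLOGY)}


def generate_kb(spec: FixtureSpec, out_dir: str | Path) -> tuple[Path, Path]:
    """Write a schema-valid bulk-import CSV pair; same seed → identical bytes."""
    model = _kb_model(spec)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    nodes: dict[tuple[str, str], str] = {}  # (label, name) -> file id

    def node(label: str, name: str) -> str:
        key = (label, name)
        if key not in nodes:
            nodes[key] = f"{label}_{len(nodes):04d}"
        return nodes[key]

    edges: list[tuple[str, str, str]] = []

    def edge(src: str, tgt: str, category: str) -> None:
        if (src, tgt, category) not in edges:
            edges.append((src, tgt, category))

    for d in model["diseases"]:
        node("disease", d)
    for drug, disease in sorted(model["drugs"].items()):
        edge(node("medication", drug), node("disease", disease), "treatment")
    for food, linked in sorted(model["foods"].items()):
        fid = node("diet", food)
        for disease in linked:
            edge(fid, node("disease", disease), "prevention")
    for disease, symptoms in sorted(model["symptoms"].items()):
        for s in symptoms:
            edge(node("disease", disease), node("symptom", s), "diagnosis")
    for disease, exams in sorted(model["exams"].items()):
        for e in exams:
            edge(node("disease", disease), node("examination", e), "examination")
    for label, name, category, disease in model["aetiology"]:
        edge(node(label, name), node("disease", disease), category)

    nodes_file, edges_file = out_dir / "kb_nodes.csv", out_dir / "kb_edges.csv"
    with open(nodes_file, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id:ID", "name", ":LABEL"])
        for (label, name), fid in nodes.items():
            writer.writerow([fid, name, label])
    with open(edges_file, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow([":START_ID", ":END_ID", ":TYPE"])
        writer.writerows(edges)
    return nodes_file, edges_file


# --------------------------------------------------------------------------
# Elder questionnaires
# --------------------------------------------------------------------------

def elder_name(index: int) -> str:
    return f"elder_{index + 1:03d}"


def generate_elder_profile(spec: FixtureSpec, index: int) -> QuestionnaireRecord:
    """A full-template questionnaire record for one elder.

    With probability ``fault_rate`` one medication is included whose treated
    disease is *omitted* from the registered diseases, exercising the
    registration-risk rule.
    """
    if index >= spec.n_elders:
        raise IndexError(f"index {index} >= n_elders {spec.n_elders}")
    model = _kb_model(spec)
    rng = _rng(spec, 100 + index)

    meds = rng.sample(sorted(model["drugs"]), k=rng.randint(1, 3))
    diseases = sorted({model["drugs"][m] for m in meds})
    faulty = rng.random() < spec.fault_rate
    if faulty:
        dropped = model["drugs"][rng.choice(meds)]
        diseases = [d for d in diseases if d != dropped]

    answers: dict[str, Any] = {}
    for key, (label, _cat, kind, _fixed) in QUESTIONNAIRE_TEMPLATE.items():
        if kind == "flag":
            answers[key] = rng.random() < 0.3
        elif kind == "attr":
            answers[key] = (round(rng.uniform(1.45, 1.80), 2)
                            if key == "height_m"
                            else round(rng.gauss(*spec.sensor_profile["weight"]), 1))
        elif kind == "list":
            answers[key] = []
        else:
            answers[key] = ""

    answers.update({
        "sex": rng.choice(["female", "male"]),
        "age": str(rng.randint(65, 95)),
        "elder_type": rng.choice(["home care", "institution care"]),
        "subsidy_type": rng.choice(["none", "basic pension", "disability"]),
        "subsidy_amount": str(rng.choice([0, 200, 500])),
        "monthly_income": str(rng.randint(15, 60) * 100),
        "income_source": rng.choice(["pension", "family support"]),
        "monthly_expenditure": str(rng.randint(10, 50) * 100),
        "marriage_status": rng.choice(["married", "widowed", "divorced"]),
        "spouse_name": f"spouse of {elder_name(index)}",
        "children": [f"child {i + 1} of {elder_name(index)}"
                     for i in range(rng.randint(0, 3))],
        "child_type": rng.choice(["son", "daughter", "both", "none"]),
        "caregiver_name": f"caregiver of {elder_name(index)}",
        "caregiver_relationship": rng.choice(["family", "professional"]),
        "living_environment": rng.sample(
            ["elevator", "stairs only", "ground floor", "handrails"], k=2),
        "residence_type": rng.choice(["apartment", "house"]),
        "smart_phone_model": rng.choice(["basic phone", "smartphone"]),
        "smartphone_usage": rng.choice(["daily", "rarely"]),
        "smart_devices": ["blood pressure monitor", "smart mattress"],
        "social_contact_frequency": rng.choice(["daily", "weekly", "monthly"]),
        "past_diseases": diseases,
        "current_medications": meds,
        "direct_chronic_history": rng.sample(
            ["father: hypertension", "mother: diabetes", "none"], k=1),
        "collateral_chronic_history": ["none"],
        "recent_examinations": [],
        "sleep_quality": rng.choice(["good sleep quality", "fair sleep quality",
                                     "poor sleep quality"]),
        "sleep_hours": f"{rng.randint(5, 9)} hours",
        "sleep_bedtime": rng.choice(["21:00", "22:00", "23:00"]),
        "sport_frequency": rng.choice(["daily", "3 times a week", "rarely"]),
        "sport_duration_minutes": str(rng.choice([15, 30, 60])),
        "psychology_mood": rng.choice(["stable", "low mood", "anxious"]),
        "psychology_life_satisfaction": rng.choice(["satisfied", "neutral"]),
        "excretion_pattern": rng.choice(["regular", "irregular"]),
        "diet_meals_per_day": rng.choice(["2 meals per day", "3 meals per day"]),
        "diet_appetite": rng.choice(["good appetite", "poor appetite"]),
        "diet_preference": rng.choice(["light diet", "salty diet", "sweet diet"]),
        "diet_supplements": rng.sample(["calcium", "vitamin d", "fish oil"],
                                       k=rng.randint(0, 2)),
    })
    return QuestionnaireRecord(
        elder_name=elder_name(index),
        answers=answers,
        timestamp="2023-06-01",
    )


# --------------------------------------------------------------------------
# Sensor streams
# --------------------------------------------------------------------------

def generate_sensor_stream(
    spec: FixtureSpec,
    elder: str,
    days: int,
    out_path: str | Path,
    start_date: str = "2023-06-02",
) -> Path:
    """One reading per device per day, drawn from the FixtureSpec's normal
    distributions and clipped to the classifiers' admissible ranges."""
    if days < 1:
        raise ValueError("days must be >= 1")
    from datetime import date, timedelta

    rng = _rng(spec, 10_000 + sum(ord(c) for c in elder))
    prof = spec.sensor_profile
    day0 = date.fromisoformat(start_date)

    def clip(x: float, lo: float, hi: float) -> float:
        return min(max(x, lo), hi)

    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    with open(out_path, "w", encoding="utf-8") as fh:
        for day in range(days):
            stamp = (day0 + timedelta(days=day)).isoformat()
            rows = [
                {"elder_name": elder, "device": "blood_pressure_monitor",
                 "timestamp": f"{stamp}T08:00:00",
                 "payload": {"sbp": round(clip(rng.gauss(*prof["sbp"]), 50, 300), 1),
                             "dbp": round(clip(rng.gauss(*prof["dbp"]), 30, 200), 1)}},
                {"elder_name": elder, "device": "glucose_meter",
                 "timestamp": f"{stamp}T07:30:00",
                 "payload": {"glucose":
                             round(clip(rng.gauss(*prof["glucose"]), 1.0, 40.0), 2)}},
                {"elder_name": elder, "device": "scale",
                 "timestamp": f"{stamp}T08:15:00",
                 "payload": {"weight_kg":
                             round(clip(rng.gauss(*prof["weight"]), 20, 300), 1)}},
            ]
            exits = rng.choice([0, 0, 0, 1, 1, 2])
            intervals, enter = [], f"{stamp}T22:30:00"
            cursor = 22.5
            for _ in range(exits):
                leave = cursor + rng.uniform(0.5, 1.5)
                intervals.append([_hhmm(stamp, cursor), _hhmm(stamp, leave)])
                cursor = leave + rng.uniform(0.1, 0.3)
            intervals.append([_hhmm(stamp, cursor), _hhmm(stamp, 30.5)])
            rows.append({"elder_name": elder, "device": "mattress",
                         "timestamp": f"{stamp}T22:30:00",
                         "payload": {"intervals": intervals}})
            for row in rows:
                fh.write(json.dumps(row, sort_keys=True) + "\n")
    return out_path


def _hhmm(date_str: str, hours: float) -> str:
    """ISO timestamp ``hours`` (possibly >24) after midnight of date_str."""
    from datetime import datetime, timedelta

    base = datetime.fromisoformat(date_str)
    return (base + timedelta(hours=hours)).isoformat()


# --------------------------------------------------------------------------
# Full fixture set
# --------------------------------------------------------------------------

def write_fixture_set(spec: FixtureSpec, out_dir: str | Path,
                      days: int = 7) -> Path:
    """Emit a complete fixture directory: KB CSVs, one questionnaire JSON per
    elder, one sensor JSONL per elder, plus the FixtureSpec itself."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    generate_kb(spec, out_dir)
    qdir, sdir = out_dir / "questionnaires", out_dir / "sensors"
    qdir.mkdir(exist_ok=True)
    sdir.mkdir(exist_ok=True)
    for i in range(spec.n_elders):
        record = generate_elder_profile(spec, i)
        with open(qdir / f"{record.elder_name}.json", "w",
                  encoding="utf-8") as fh:
            json.dump({"elder_name": record.elder_name,
                       "answers": record.answers,
                       "timestamp": record.timestamp},
                      fh, indent=1, sort_keys=True)
        generate_sensor_stream(spec, record.elder_name, days,
                               sdir / f"{record.elder_name}.jsonl")
    with open(out_dir / "fixture_spec.json", "w", encoding="utf-8") as fh:
        fh.write(spec.model_dump_json(indent=1))
    return out_dir
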