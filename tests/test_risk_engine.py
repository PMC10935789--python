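"""Registration, care and medical risk screening."""

import random

import pytest

from carekg import (KnowledgeGraph, NotFoundError, QuestionnaireRecord,
                    SensorReading, apply_sensor_reading,
                    check_registration_risk, find_care_risks,
                    find_medical_risks, load_questionnaire)
from carekg.risk import AETIOLOGY_CATEGORIES, LIFESTYLE_LABELS


def _graph(meds=(), diseases=(), diets=()):
    g = KnowledgeGraph()
    load_questionnaire(g, QuestionnaireRecord(
        "elder A",
        {"current_medications": list(meds), "past_diseases": list(diseases)},
        "2023-06-01"))
    m = g.add_node("medication", "nifedipine")
    d = g.add_node("disease", "hypertension")
    g.add_edge(m, d, "treatment")
    elder = g.find_node("name", "elder A").id
    for diet in diets:
        g.add_edge(elder, g.add_node("diet", diet), "diet_information")
    return g


class TestRegistrationRisk:
    def test_drug_without_disease_warns(self):
        findings = check_registration_risk(_graph(meds=["nifedipine"]), "elder A")
        assert len(findings) == 1
        assert findings[0].severity == "warning"
        assert "hypertension" in findings[0].message

    def test_registered_disease_silences(self):
        g = _graph(meds=["nifedipine"], diseases=["hypertension"])
        assert check_registration_risk(g, "elder A") == []

    def test_no_medications_vacuous(self):
        assert check_registration_risk(_graph(), "elder A") == []

    def test_missing_elder(self):
        with pytest.raises(NotFoundError):
            check_registration_risk(_graph(), "elder Z")

    def test_adding_missing_edge_removes_exactly_that_finding(self):
        g = _graph(meds=["nifedipine"])
        before = check_registration_risk(g, "elder A")
        assert len(before) == 1
        elder = g.find_node("name", "elder A").id
        disease = g.find_node("disease", "hypertension").id
        g.add_edge(elder, disease, "basic_information")
        assert check_registration_risk(g, "elder A") == []

    @pytest.mark.parametrize("seed", range(5))
    def test_truth_table_against_brute_force(self, seed, kb_graph):
        """Findings == brute-force (fR1 and fR2 and not fR3) over all
        (elder, drug, disease) triples."""
        rng = random.Random(seed)
        drugs = kb_graph.nodes("medication")
        diseases = kb_graph.nodes("disease")
        elders = []
        for i in range(4):
            name = f"elder {seed}-{i}"
            elders.append(load_questionnaire(
                kb_graph, QuestionnaireRecord(name, {}, "2023-06-01")))
            for m in rng.sample(drugs, 3):
                kb_graph.add_edge(elders[-1], m.id, "basic_information")
            for d in rng.sample(diseases, 2):
                kb_graph.add_edge(elders[-1], d.id, "basic_information")

        for elder_id in elders:
            elder = kb_graph.get_node(elder_id)
            expect = set()
            for m in drugs:
                fr1 = kb_graph.has_edge(elder_id, m.id, "basic_information")
                for d in diseases:
                    fr2 = (kb_graph.has_edge(m.id, d.id, "treatment")
                           or kb_graph.has_edge(d.id, m.id, "treatment"))
                    fr3 = any(kb_graph.has_edge(a, b, c)
                              for c in ("basic_information", "diagnosis")
                              for a, b in ((elder_id, d.id), (d.id, elder_id)))
                    if fr1 and fr2 and not fr3:
                        expect.add((m.key, d.key))
            got = set()
            for f in check_registration_risk(kb_graph, elder.name):
                med = next(kb_graph.get_node(e.source if "medication" in e.source
                                             else e.target)
                           for e in f.evidence if "medication" in e.source
                           or "medication" in e.target)
                dis = next(kb_graph.get_node(e.source if "disease" in e.source
                                             else e.target)
                           for e in f.evidence if "disease" in e.source
                           or "disease" in e.target)
                got.add((med.key, dis.key))
            assert got == expect


class TestCareRisk:
    def test_case_paths_found(self, case_graph):
        findings = find_care_risks(case_graph, "elder_demo")
        text = " ".join(f.message for f in findings)
        assert "hyperlipidemia" in text          # via poor sleep quality
        assert "coronary heart disease" in text  # via overweight
        assert all(f.category == "care" for f in findings)

    def test_evidence_edges_exist(self, case_graph):
        for f in find_care_risks(case_graph, "elder_demo"):
            for e in f.evidence:
                assert case_graph.has_edge(e.source, e.target, e.category)

    def test_deterministic_order(self, case_graph):
        a = [f.message for f in find_care_risks(case_graph, "elder_demo")]
        b = [f.message for f in find_care_risks(case_graph, "elder_demo")]
        assert a == b

    @pytest.mark.parametrize("seed", range(6))
    def test_equals_brute_force_enumeration(self, seed):
        """Care findings == exhaustive simple-path enumeration restricted to
        lifestyle intermediates and aetiology closing edges."""
        g = _random_lifestyle_graph(seed)
        elder = g.find_node("name", "elder A").id

        adjacency: dict[str, list] = {}
        for e in g.edges():
            adjacency.setdefault(e.source, []).append((e.target, e))
            adjacency.setdefault(e.target, []).append((e.source, e))

        expect = set()

        def walk(node, visited, edges):
            if len(edges) > 3:
                return
            if (edges and g.get_node(node).label == "disease"
                    and len(edges) >= 2
                    and edges[-1].category in AETIOLOGY_CATEGORIES
                    and all(g.get_node(v).label in LIFESTYLE_LABELS
                            for v in visited[1:-1])):
                expect.add(tuple(visited))
            if len(edges) == 3:
                return
            for nbr, edge in adjacency.get(node, []):
                if nbr not in visited:
                    walk(nbr, visited + [nbr], edges + [edge])

        walk(elder, [elder], [])
        got = set()
        for f in find_care_risks(g, "elder A", max_depth=3):
            nodes = [elder]
            for e in f.evidence:
                nodes.append(e.target if e.source == nodes[-1] else e.source)
            got.add(tuple(nodes))
        assert got == expect


def _random_lifestyle_graph(seed):
    rng = random.Random(seed)
    g = KnowledgeGraph()
    elder = g.add_node("name", "elder A")
    mids = []
    for label in ("sleep", "diet", "sport", "psychology", "physical_index"):
        for i in range(rng.randint(1, 3)):
            mids.append((label, g.add_node(label, f"{label} {i}")))
    diseases = [g.add_node("disease", f"disease {i}")
                for i in range(rng.randint(2, 6))]
    for label, mid in mids:
        if rng.random() < 0.7:
            cat = ("diet_information" if label == "diet"
                   else "physical_information")
            g.add_edge(elder, mid, cat)
        for d in diseases:
            if rng.random() < 0.3:
                cat = rng.choice(["initiation", "prevention"])
                if g.schema.allows_edge(label, "disease", cat):
                    g.add_edge(mid, d, cat)
    for a in diseases:
        for b in diseases:
            if a != b and rng.random() < 0.15:
                g.add_edge(a, b, "complication")
    return g


class TestMedicalRisk:
    def _elder_graph(self, kb_graph, meds=(), diets=()):
        elder = load_questionnaire(kb_graph, QuestionnaireRecord(
            "elder M", {"current_medications": list(meds)}, "2023-06-01"))
        for diet in diets:
            kb_graph.add_edge(elder, kb_graph.add_node("diet", diet),
                              "diet_information")
        return kb_graph

    def test_second_degree_bp_materializes_diagnosis(self, kb_graph):
        g = self._elder_graph(kb_graph)
        apply_sensor_reading(g, SensorReading(
            "elder M", "blood_pressure_monitor", "2023-06-02T08:00:00",
            {"sbp": 150, "dbp": 95}))
        findings = find_medical_risks(g, "elder M")
        threshold = [f for f in findings
                     if f.rule_id == "sensor-threshold-blood_pressure"]
        assert len(threshold) == 1
        assert threshold[0].severity == "critical"
        elder = g.find_node("name", "elder M").id
        disease = g.find_node("disease", "hypertension").id
        assert g.has_edge(elder, disease, "diagnosis")
        category = g.find_node("physical_index", "2nd degree hypertension").id
        assert g.has_edge(category, disease, "diagnosis")

    def test_no_data_no_findings(self, kb_graph):
        g = self._elder_graph(kb_graph)
        assert find_medical_risks(g, "elder M") == []

    def test_interacting_drug_pair_single_finding(self, kb_graph):
        g = self._elder_graph(kb_graph, meds=["aspirin", "warfarin"])
        findings = [f for f in find_medical_risks(g, "elder M")
                    if f.rule_id == "drug-drug-interaction"]
        assert len(findings) == 1

    def test_diet_drug_interaction(self, kb_graph):
        g = self._elder_graph(kb_graph, meds=["nifedipine"],
                              diets=["grapefruit"])
        findings = [f for f in find_medical_risks(g, "elder M")
                    if f.rule_id == "diet-drug-interaction"]
        assert len(findings) == 1
        assert "grapefruit" in findings[0].message

    def test_evidence_soundness(self, kb_graph):
        g = self._elder_graph(kb_graph, meds=["aspirin", "warfarin"])
        apply_sensor_reading(g, SensorReading(
            "elder M", "glucose_meter", "2023-06-02T07:30:00",
            {"glucose": 11.5}))
        for f in find_medical_risks(g, "elder M"):
            for e in f.evidence:
                assert (g.has_edge(e.source, e.target, e.category)
                        or g.has_edge(e.target, e.source, e.category))
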