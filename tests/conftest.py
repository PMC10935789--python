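import pytest

from carekg import (FixtureSpec, KnowledgeGraph, QuestionnaireRecord,
                    generate_kb, load_kb_triples, load_questionnaire)


@pytest.fixture(scope="session")
def spec():
    return FixtureSpec(seed=11, n_elders=6, fault_rate=0.5)


@pytest.fixture(scope="session")
def kb_files(spec, tmp_path_factory):
    return generate_kb(spec, tmp_path_factory.mktemp("kb"))


@pytest.fixture
def kb_graph(kb_files):
    """A fresh graph holding the synthetic knowledge base (curated core plus
    seeded synthetic concepts)."""
    graph = KnowledgeGraph()
    summary = load_kb_triples(graph, *kb_files)
    assert not summary.violations
    return graph


@pytest.fixture
def case_graph(kb_graph):
    """KB plus one elder mirroring the worked case: registered hypertension,
    an antihypertensive, poor sleep quality and an overweight body index."""
    record = QuestionnaireRecord(
        elder_name="elder_demo",
        answers={
            "sex": "female",
            "age": "78",
            "past_diseases": ["hypertension"],
            "current_medications": ["nifedipine"],
            "sleep_quality": "poor sleep quality",
            "index_overweight": True,
            "condition_constipation": True,
            "diet_preference": "light diet",
        },
        timestamp="2023-06-01",
    )
    load_questionnaire(kb_graph, record)
    return kb_graph
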