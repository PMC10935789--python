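# carekg

A knowledge-graph engine for smart elderly chronic-disease care: it fuses
curated care knowledge, elder questionnaires and home-sensor telemetry into
one schema-constrained graph, keeps that graph current as vitals stream in,
and from it identifies care risks, generates structured care reports and
answers natural-language care questions deterministically.

Intended audience: researchers and engineers building decision-support
tooling for community/institutional elderly care, and anyone who wants a
fully testable, dependency-light reference implementation of
knowledge-graph-driven care logic.

## Core model

The knowledge graph is a labelled directed property graph

```
KG = (N, R, A, fN, fR)
```

with node set N over 31 labels (elder demographics, lifestyle, diseases,
medications, symptoms, examinations, devices, environment…), edge set R
over 9 relation categories (`basic_information`, `physical_information`,
`diet_information`, `initiation`, `prevention`, `treatment`, `diagnosis`,
`complication`, `examination`), attribute set A, and constraint maps fN
(label → permitted attributes) and fR (permitted
(source-label, target-label, category) patterns). The schema ships as data
(`src/carekg/data/schema.yaml`) and every mutation is checked against it.

On top of the graph:

* **Sensor transforms** classify blood pressure, fasting glucose, BMI and
  smart-mattress bed-rest behaviour against chronic-disease care-guideline
  thresholds (e.g. 2nd-degree hypertension at SBP ≥ 140 or DBP ≥ 90 mmHg,
  obesity at BMI ≥ 28 kg/m², poor glycaemic control from 10.0 mmol/L).
* **Dynamic updating** maintains exactly one `physical_information` edge
  per elder and sensor family, rewiring it only when a reading crosses a
  category boundary; raw readings go to a log.
* **Risk identification** covers registration consistency (elder takes a
  drug that treats a disease the elder is not registered with:
  fR1 ∧ fR2 ∧ ¬fR3), care risks (lifestyle → disease aetiology paths of
  length ≤ 3), and medical risks (threshold exceedance, drug–drug and
  diet–drug interactions).
* **Report generation** renders a three-chapter care report (basic /
  health / diet information), each chapter with risk identification and
  care recommendations.
* **Question answering** maps a free-text question to one of eight domain
  classes, emits a Cypher-style query, executes it on the graph and
  templates an answer sentence.
* **Synthetic fixtures** generate a seeded knowledge base, elder
  questionnaires and sensor streams so the whole pipeline runs and is
  tested without any private data.

See `docs/methods.md` for the full method description, every threshold,
and the design decisions behind them.

## Worked example

End to end from the command line, entirely on synthetic data:

```
$ carekg --data-dir demo simulate --seed 7 --elders 4 --days 2
fixtures written to demo/fixtures
$ carekg --data-dir demo build
KB: 78 nodes, 96 edges, 0 skipped rows
questionnaires loaded: 4
graph saved: 213 nodes, 515 edges
$ carekg --data-dir demo update
readings applied: 32; rewires: 5
$ carekg --data-dir demo ask "What drugs treat hypertension?"
Medications used to treat hypertension: metoprolol, nifedipine.
```

With `--log-level INFO` the `ask` command also prints the query it built:

```
MATCH p = (m:Disease)-[r:TREATS]-(n:Medication) where m.name = 'hypertension' return p
```

Risk identification and reporting:

```
$ carekg --data-dir demo risks elder_001
[care/info] elder_001 may be at risk of coronary heart disease via overweight (initiation).
[care/info] elder_001 may be at risk of hypertension via high salt diet (initiation).
...
$ carekg --data-dir demo report elder_001
# Care report: elder_001
...
```

The same pipeline from Python:

```python
from carekg import (FixtureSpec, KnowledgeGraph, answer_question,
                    generate_kb, load_kb_triples)

graph = KnowledgeGraph()
load_kb_triples(graph, *generate_kb(FixtureSpec(seed=7), "demo/fixtures"))
answer = answer_question(graph, "What is better to eat for hypertension?")
print(answer.sentence)
# For hypertension, the following foods are suitable: celery, low salt diet,
# oat, synthetic food 01.
```

Other subcommands: `validate` (schema + registration audit; findings are
data, exit status stays 0), `export` (bulk-import CSV pair).

## Layout

```
src/carekg/        package modules (graph, schema, transform, ingest,
                   risk, report, qa, fixtures, cli, errors)
src/carekg/data/   schema, thresholds, rules, domain tree, aliases,
                   templates, interaction tables (all YAML/CSV)
tests/             unit + property + oracle + acceptance tests
scripts/           acceptance.py (see above)
docs/methods.md    methods, parameters, assumptions, limitations
```

## Limitations

Interaction tables and the questionnaire template are illustrative
package fixtures, not clinical references; synthetic vitals have no
physiological time structure; the QA layer is dictionary-based English.
See the limitations section of `docs/methods.md`.
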