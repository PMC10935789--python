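# Methods

## The model

`carekg` implements a smart-care engine for elderly chronic-disease care
built around a labelled, directed property graph

KG = (N, R, A, fN, fR)

where N are typed nodes drawn from a closed set of 31 labels (demographics
such as `name`, `sex`, `age`; lifestyle such as `diet`, `sleep`, `sport`,
`psychology`; medical such as `disease`, `medication`, `symptom`,
`examination`; and context such as `living_environment`, `smart_device`),
R are 9 relation categories (`basic_information`, `physical_information`,
`diet_information`, `initiation`, `prevention`, `treatment`, `diagnosis`,
`complication`, `examination`), A are node attributes, fN maps each label
to its permitted attribute keys, and fR whitelists which
(source-label, target-label, category) triples may exist.  The concept
layer ships as `data/schema.yaml` and every mutation is validated against
it, so any graph reachable through the public API is schema-clean by
construction; `validate_schema` re-checks the whole graph and *reports*
violations (for data that bypassed the API, e.g. hand-edited CSVs).

Node identity is (label, case-folded whitespace-collapsed name).  This is a
design choice the source material leaves open; it is what lets a
questionnaire answer "hypertension", a curated triple about Hypertension
and a sensor-derived diagnosis all land on one concept node.  Edges are
stored directed but matched and path-searched undirected by default,
because care queries are naturally symmetric (a `treatment` edge answers
both "what treats X" and "what is Y for"); a direction flag exists on the
path search.

## Data ingestion

Three sources feed the graph:

* **Curated knowledge** in a Neo4j-style bulk-import CSV dialect
  (`id:ID,name,:LABEL,attr…` / `:START_ID,:END_ID,:TYPE,attr…`).  Loading
  is an upsert; malformed or schema-violating rows are skipped and
  reported, never raised.  `export_graph` writes the same dialect and the
  round trip is lossless (numeric attributes are re-parsed on load).
* **Questionnaires**: one JSON record per elder against a shipped template
  of 104 question fields grouped into basic / health / diet chapters.  The
  original >100-item instrument is not public, so the template is defined
  here, with one declarative mapping row per field (question key → node
  label, relation category, value handling: free value, boolean flag with a
  fixed concept name, list, or elder attribute).  Unanswered fields create
  nothing.
* **Sensor streams**: JSON Lines, one reading per line, from four device
  types (blood-pressure monitor, glucose meter, scale, mattress).

## Sensor classification (thresholds.yaml)

Classification standards follow Chinese chronic-disease care guidelines:

| family | categories | boundaries |
|---|---|---|
| blood pressure | normal / 1st / 2nd degree | 1st: SBP ≥ 130 or DBP ≥ 80; 2nd: SBP ≥ 140 or DBP ≥ 90 (mmHg) |
| fasting glucose | BelowRange / Good / Normal / Fair / Poor / ExtremelyPoor | 4.4, 6.1, 7.2, 8.2, 10.0 mmol/L |
| BMI | underweight / normal / overweight / obesity | 18.5, 24.0, 28.0 kg/m² |
| mattress | normal / abnormal bed rest | > 3 night exits or > 10 h continuous lying |

Conventions the printed standards leave open, fixed here as explicit
choices:

* blood pressure combines SBP and DBP with **OR** and takes the highest
  satisfied degree, the usual hypertension-guideline reading of stacked
  thresholds;
* glucose bands are half-open [low, high), resolving boundary values
  (6.1, 7.2, 10.0) upward deterministically; the uncovered strip
  [8.2, 8.3) between the printed Fair ceiling and Poor floor is normalised
  into Poor so the classifier is total;
* glucose below 4.4 is a distinct BelowRange category with a
  `hypoglycemia` flag; its severity degree stays 0 so that degree remains
  monotone in the measured value within each family (0 = best);
* BMI severity ranks are normal 0, underweight/overweight 1, obesity 2 —
  monotone in BMI above 18.5, and making obesity the single most severe
  class;
* the mattress thresholds (3 exits, 10 h) are package defaults — the
  guideline names the indicators but prints no cut-offs — and are
  configurable in `thresholds.yaml`, which is the single source of truth
  for all of the above.

## Dynamic updating (edge rewiring)

Per elder and sensor family, the graph holds exactly **one**
`physical_information` edge to a `physical_index` category node ("normal
blood pressure", "2nd degree hypertension", …).  A new reading is
classified; if the category changed, the stale edge is removed and an edge
to the new category node added, atomically within the update call.  Raw
readings are appended to an elder-level log kept outside the graph (the
graph stores current state, not trajectories — retaining the category
history as graph structure is a known extension, deliberately not done
here).  Equal-timestamp readings resolve by input order, last one winning.

## Risk identification

* **Registration risk** evaluates the truth table fR1 ∧ fR2 ∧ ¬fR3 per
  (elder, drug, disease) triple: the elder takes a drug, the drug treats a
  disease, the elder has no `basic_information` or `diagnosis` link to that
  disease → one warning per (drug, disease) pair.  Rules are declarative
  (`rules.yaml`: a hop chain plus an absent-edge condition), so the same
  machinery extends to other consistency checks.
* **Care risk** enumerates simple undirected paths of length 2–3 from the
  elder, through lifestyle/body-state intermediates only (`diet`, `sleep`,
  `psychology`, `psychological_factor`, `sport`, `physical_index`,
  `physical_condition`), ending at a `disease` via an `initiation`,
  `prevention` or `complication` edge.  One finding per path; the path is
  the evidence.  The search is a hand-written bounded DFS with
  deterministic lexicographic ordering; tests cross-check it against
  `networkx.all_simple_paths` enumeration.
* **Medical risk**: (a) a current sensor category at or above a configured
  severity emits a finding and materialises provisional `diagnosis` edges
  (category node → disease and elder → disease, tagged
  `provenance: sensor-risk` since the source material does not say whether
  such edges are permanent); the default mapping is blood pressure
  degree ≥ 2 → hypertension (the 140/90 formula), glucose degree ≥ 3
  (Poor) → diabetes, BMI degree ≥ 2 (obesity) → hyperlipidemia, the latter
  two being package defaults; (b) drug–drug pairs and (c) diet–drug pairs
  from two fixture CSV interaction tables (the risk classes are real, the
  specific pairs are illustrative fixtures — no authoritative pair list was
  available).  Severity: registration → warning, threshold degree ≥ 2 →
  critical, interactions → warning, care paths → info; the scale itself is
  a package choice.

## Report generation

A report has exactly three chapters — basic, health, diet information —
each with exactly two subsections (risk identification, care
recommendations) plus a retrieved profile, regardless of data sparsity.
Findings are partitioned by scope: registration → chapter 1; diet-related
(diet-first care paths, diet–drug interactions) → chapter 3; everything
else → chapter 2.  Recommendations are `str.format` templates
(`report_templates.yaml`) bound to graph retrievals: prevention-linked
foods and habits, examination reminders, and a measurement reminder when a
monitored disease (hypertension/diabetes) has no current sensor category.
The report never names a disease outside the elder's findings or
registered conditions.  Rendering to Markdown and JSON is deterministic;
JSON round-trips losslessly.

## Question answering

Deterministic pipeline: feature dictionary (every node name plus an alias
table) → longest-match entity recognition with span masking → domain-tree
classification (first leaf, in file priority order, whose word-boundary
trigger phrases fire and whose required entity label is present) → query
construction → templated answer.  Eight question classes ship
(`disease_drug`, `disease_food`, `disease_symptom`, `disease_cause`,
`disease_prevention`, `disease_examination`, `drug_disease`,
`symptom_disease`).  The emitted query string uses the Cypher dialect,
e.g. for the drug question bound to hypertension:

    MATCH p = (m:Disease)-[r:TREATS]-(n:Medication) where m.name = 'hypertension' return p

and `parse_query` inverts the emission, so tests can assert that every
emitted string parses back to the executed pattern.  Entity recognition is
dictionary-based rather than learned — determinism is required for a
testable contract — but a model-backed matcher can be slotted in behind
`classify_question`.  Unanswerable questions (no entity, no class, empty
result) return a fixed fallback sentence, never an exception.

## Synthetic data

The generators emulate the three sources with a single explicit seed
threaded everywhere.  A curated core — the six chronic diseases of the
worked case (hypertension, hyperlipidemia, coronary heart disease,
diabetes, Alzheimer's disease, cerebrovascular disease), eight drugs,
preventive foods, symptoms, examinations and the case's aetiology links
(poor sleep quality → hyperlipidemia, overweight → coronary heart disease,
hyperlipidemia → coronary heart disease, …) — is embedded verbatim so
worked-example behaviour is seed-independent; synthetic
diseases/drugs/foods/symptoms fill up to the configured counts (defaults:
20 elders as in the trial the system was piloted on, 12 diseases, 20
drugs, 15 foods, 18 symptoms, edge density 0.15).  Elder profiles answer
the full questionnaire template; with probability `fault_rate` (default
0.25) one medication's treated disease is omitted from the registration,
exercising the registration-risk rule; sensor streams draw one reading per
device per day from configurable normal distributions clipped to the
classifiers' admissible ranges.

What the generators do **not** model: physiological autocorrelation or
circadian structure in vitals, medication effects on readings, missing or
corrupted telemetry, Chinese-language questionnaire text, and realistic
co-morbidity structure.  Passing tests therefore demonstrate the engine's
logic (schema enforcement, classification boundaries, rule truth tables,
determinism), not clinical validity on real cohorts.

## Numerical and procedural choices

* All orderings (paths, matches, findings, answers) are lexicographic on
  canonical names — identical inputs give byte-identical outputs.
* Classifier inputs are range-checked (SBP 50–300, DBP 30–200 mmHg,
  glucose 1–40 mmol/L, weight 20–300 kg, height 1.0–2.5 m); out-of-range
  raises an input error rather than extrapolating.
* Boundary tests scale BMI grids through height 2 m so the weight → BMI
  division by 4 is float-exact.
* Degenerate inputs: an empty graph validates clean; an elder with no data
  yields an empty three-chapter report; duplicate node/edge insertion is an
  upsert/no-op.
* Problem sizes in tests (graphs ≤ 40 nodes, 100 random seeds for the
  path-oracle check, 1000 readings for the rewiring invariant) keep the
  whole suite around a few seconds while covering every boundary value
  printed in the guideline table exhaustively.

## Known limitations

* The per-label attribute inventory (fN) is not authoritatively defined
  anywhere; `schema.yaml` ships a minimal practical set and is editable.
* Interaction tables are illustrative fixtures, not a pharmacological
  reference.
* Only current sensor state lives in the graph; category history is in the
  reading log, not queryable as graph structure.
* The QA dictionary is English with an alias table; the deployed source
  system this models is Chinese-language.
* Knowledge enters exclusively through curated triple files; there is no
  machine-learning extraction from nursing literature.
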