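# Sensor-to-category transformation standards (Chinese chronic-disease care
# guidelines). This file is the single source of truth for the classifiers.

blood_pressure:
  # degree = highest degree whose SBP OR DBP condition is met; 0 = normal
  degrees:
    - {degree: 1, name: 1st degree hypertension, sbp: 130, dbp: 80}
    - {degree: 2, name: 2nd degree hypertension, sbp: 140, dbp: 90}
  normal_name: normal blood pressure
  input_range: {sbp: [50, 300], dbp: [30, 200]}

glucose:
  # fasting blood glucose, mmol/L; half-open intervals [low, high).
  # The printed standard leaves [8.2, 8.3) uncovered; it is normalized into
  # Poor so the classifier is total.
  categories:
    - {name: BelowRange, low: null, high: 4.4, degree: 0, flags: [hypoglycemia]}
    - {name: Good, low: 4.4, high: 6.1, degree: 0}
    - {name: Normal, low: 6.1, high: 7.2, degree: 1}
    - {name: Fair, low: 7.2, high: 8.2, degree: 2}
    - {name: Poor, low: 8.2, high: 10.0, degree: 3}
    - {name: ExtremelyPoor, low: 10.0, high: null, degree: 4}
  node_names:
    BelowRange: low blood glucose
    Good: good blood glucose
    Normal: normal blood glucose
    Fair: fair blood glucose
    Poor: poor blood glucose
    ExtremelyPoor: extremely poor blood glucose
  input_range: [1.0, 40.0]

bmi:
  categories:
    - {name: Underweight, low: null, high: 18.5, degree: 1}
    - {name: Normal weight, low: 18.5, high: 24.0, degree: 0}
    - {name: Overweight, low: 24.0, high: 28.0, degree: 1}
    - {name: Obesity, low: 28.0, high: null, degree: 2}
  node_names:
    Underweight: underweight
    Normal weight: normal weight
    Overweight: overweight
    Obesity: obesity
  input_range: {weight: [20, 300], height: [1.0, 2.5]}

mattress:
  # thresholds are artifact defaults; the guideline names the indicators
  # (nighttime frequency, prolonged lying time) without printing cut-offs
  night_window: ["22:00", "06:00"]
  max_night_exits: 3        # F: flag if exit count strictly exceeds
  max_lying_hours: 10.0     # H: flag if longest continuous lying exceeds
  node_names:
    normal: normal bed rest
    flagged: abnormal bed rest

# medical-risk escalation: which category degree materializes which diagnosis
risk:
  blood_pressure: {min_degree: 2, disease: hypertension}
  glucose: {min_degree: 3, disease: diabetes}
  bmi: {min_degree: 2, disease: hyperlipidemia}
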