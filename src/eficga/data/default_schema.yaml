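# Default eFI-CGA coding schema.
#
# One entry per Comprehensive Geriatric Assessment item.  Each raw response
# maps to a coded deficit value in [0, 1] (closer to 1 = greater risk).
# Ordinal items use the three-level 0 / 0.5 / 1 coding; integer items are
# coded through ordered bands (first band whose "upto" covers the value
# wins; "upto: null" = no upper bound).  The "Number of Problems"
# comorbidity count has no coding map: the raw count enters the score
# numerator capped at comorbidity_cap, and the cap enters the denominator.
#
# This file is the scoring ground truth and is meant to be audited and,
# where a site's coding scheme differs, replaced (see `eficga schema export`
# for a flat per-value audit table).
schema_version: "1.0"
comorbidity_cap: 18
threshold: 0.80
dependencies:
  - when_item: falls
    equals: "No"
    set_item: number_of_falls
    value: 0
items:
  - id: cognition
    label: Cognition
    section: Cognition
    kind: categorical
    action_flaggable: true
    choices:
      - {value: Normal, coded: 0.0}
      - {value: Mildly Impaired, coded: 0.5}
      - {value: Severely Impaired, coded: 1.0}
  - id: cognitive_score
    label: Cognitive Test Score
    section: Cognition
    kind: numeric
    min: 0
    max: 30
    bands:
      - {upto: 19, coded: 1.0}
      - {upto: 24, coded: 0.5}
      - {upto: null, coded: 0.0}
  - id: emotion
    label: Emotion
    section: Mood
    kind: categorical
    action_flaggable: true
    choices:
      - {value: Good, coded: 0.0}
      - {value: Low Mood Sometimes, coded: 0.5}
      - {value: Depressed, coded: 1.0}
  - id: motivation
    label: Motivation
    section: Mood
    kind: categorical
    choices:
      - {value: High, coded: 0.0}
      - {value: Usual, coded: 0.5}
      - {value: Low, coded: 1.0}
  - id: health_attitude
    label: Health Attitude
    section: Mood
    kind: categorical
    choices:
      - {value: Positive, coded: 0.0}
      - {value: Neutral, coded: 0.5}
      - {value: Negative, coded: 1.0}
  - id: vision
    label: Vision
    section: Senses & Communication
    kind: categorical
    action_flaggable: true
    choices:
      - {value: Normal, coded: 0.0}
      - {value: Impaired, coded: 0.5}
      - {value: Severely Impaired, coded: 1.0}
  - id: hearing
    label: Hearing
    section: Senses & Communication
    kind: categorical
    action_flaggable: true
    choices:
      - {value: Normal, coded: 0.0}
      - {value: Impaired, coded: 0.5}
      - {value: Severely Impaired, coded: 1.0}
  - id: speech
    label: Speech
    section: Senses & Communication
    kind: categorical
    choices:
      - {value: Normal, coded: 0.0}
      - {value: Impaired, coded: 0.5}
      - {value: Severely Impaired, coded: 1.0}
  - id: sleep
    label: Sleep
    section: Symptoms
    kind: categorical
    action_flaggable: true
    choices:
      - {value: Normal, coded: 0.0}
      - {value: Disturbed, coded: 0.5}
      - {value: Severely Disturbed, coded: 1.0}
  - id: pain
    label: Pain
    section: Symptoms
    kind: categorical
    action_flaggable: true
    choices:
      - {value: None, coded: 0.0}
      - {value: Mild, coded: 0.5}
      - {value: Severe, coded: 1.0}
  - id: strength
    label: Strength
    section: Mobility
    kind: categorical
    choices:
      - {value: Normal, coded: 0.0}
      - {value: Reduced, coded: 0.5}
      - {value: Very Weak, coded: 1.0}
  - id: balance
    label: Balance
    section: Mobility
    kind: categorical
    choices:
      - {value: Steady, coded: 0.0}
      - {value: Unsteady, coded: 0.5}
      - {value: Falls Risk, coded: 1.0}
  - id: mobility
    label: Mobility
    section: Mobility
    kind: categorical
    action_flaggable: true
    choices:
      - {value: Independent, coded: 0.0}
      - {value: Uses Aid, coded: 0.5}
      - {value: Dependent, coded: 1.0}
  - id: falls
    label: Falls
    section: Falls
    kind: categorical
    action_flaggable: true
    choices:
      - {value: "No", coded: 0.0}
      - {value: "Yes", coded: 1.0}
  - id: number_of_falls
    label: Number of Falls
    section: Falls
    kind: count
    min: 0
    max: 30
    bands:
      - {upto: 0, coded: 0.0}
      - {upto: 1, coded: 0.5}
      - {upto: null, coded: 1.0}
  - id: adl
    label: Activities of Daily Living
    section: Function
    kind: categorical
    action_flaggable: true
    choices:
      - {value: Independent, coded: 0.0}
      - {value: Needs Some Help, coded: 0.5}
      - {value: Dependent, coded: 1.0}
  - id: appetite
    label: Appetite
    section: Nutrition
    kind: categorical
    action_flaggable: true
    choices:
      - {value: Good, coded: 0.0}
      - {value: Fair, coded: 0.5}
      - {value: Poor, coded: 1.0}
  - id: weight_loss
    label: Recent Weight Loss
    section: Nutrition
    kind: categorical
    action_flaggable: true
    choices:
      - {value: "No", coded: 0.0}
      - {value: Some, coded: 0.5}
      - {value: Marked, coded: 1.0}
  - id: social_engagement
    label: Social Engagement
    section: Social
    kind: categorical
    action_flaggable: true
    choices:
      - {value: Active, coded: 0.0}
      - {value: Limited, coded: 0.5}
      - {value: Isolated, coded: 1.0}
  - id: control_of_life
    label: Control of Life
    section: Social
    kind: categorical
    choices:
      - {value: Full, coded: 0.0}
      - {value: Partial, coded: 0.5}
      - {value: "None", coded: 1.0}
  - id: medication_use
    label: Medication
    section: Medical
    kind: categorical
    action_flaggable: true
    choices:
      - {value: "None", coded: 0.0}
      - {value: One To Four, coded: 0.5}
      - {value: Five Or More, coded: 1.0}
  - id: cfs
    label: Clinical Frailty Scale
    section: Medical
    kind: numeric
    min: 1
    max: 9
    bands:
      - {upto: 3, coded: 0.0}
      - {upto: 5, coded: 0.5}
      - {upto: null, coded: 1.0}
  - id: number_of_problems
    label: Number of Problems
    section: Medical
    kind: comorbidity_count
    min: 0
    max: 30
  - id: comorbidity_notes
    label: Comorbidity Notes
    section: Medical
    kind: non_scored
    required: false
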