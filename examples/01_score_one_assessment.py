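"""Score a single CGA encounter with the default coding schema.

Builds one assessment programmatically, computes the frailty index, and
shows the audit trail the scorer returns.
"""

import datetime as dt

from eficga import Assessment, Demographics, default_schema, score_assessment

schema = default_schema()

assessment = Assessment(
    schema=schema,
    demographics=Demographics(
        healthcare_number="HC12345678",
        age=81,
        gender="Female",
        education="10",
        clinician_id="CL042",
        assessment_date=dt.date(2026, 9, 26),
        assessment_time=dt.time(10, 30),
    ),
)

assessment.set_responses(
    {
        "cognition": "Mildly Impaired",
        "cognitive_score": 23,
        "emotion": "Good",
        "motivation": "Usual",
        "health_attitude": "Positive",
        "vision": "Impaired",
        "hearing": "Normal",
        "speech": "Normal",
        "sleep": "Disturbed",
        "pain": "Mild",
        "strength": "Reduced",
        "balance": "Unsteady",
        "mobility": "Uses Aid",
        "falls": "No",  # forces Number of Falls to 0 automatically
        "adl": "Independent",
        "appetite": "Good",
        "weight_loss": "No",
        "social_engagement": "Limited",
        "control_of_life": "Full",
        "medication_use": "Five Or More",
        "cfs": 4,
        "number_of_problems": 7,
    }
)
assessment.flag_action("mobility", "refer to physiotherapy")

result = score_assessment(assessment)

print(f"eFI-CGA score : {result.score:.4f}")
print(f"numerator     : {result.numerator}  (sum of coded deficits, comorbidities capped at 18)")
print(f"denominator   : {result.denominator}  (answered items + the comorbidity cap)")
print(f"completeness  : {result.completeness:.1%} of required fields answered")
print(f"items missing : {list(result.items_missing) or 'none'}")

# The score is the deficit-accumulation ratio: a value of ~0.30 sits in the
# moderately frail range (0 = no deficits present, 1 = every deficit at its worst).
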