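# eficga — a schema-driven electronic frailty index (eFI-CGA) calculator

`eficga` computes the deficit-accumulation Frailty Index from
Comprehensive Geriatric Assessment (CGA) responses. It is aimed at
clinical informatics teams and frailty researchers who need a headless,
auditable, scriptable scoring engine: the same calculation a geriatrician
performs by hand with the CGA form and a coding table, but automated,
validated, and persisted in spreadsheet-friendly records.

## The score

Frailty is operationalised as the proportion of health deficits present
out of those evaluated:

```
eFI-CGA = Σᵢ xᵢ / n
```

where each answered item contributes a coded deficit `xᵢ ∈ [0, 1]`
(0 = no deficit, 1 = fully present) and `n` is the total number of
deficits under evaluation. Two rules shape the ratio:

* **Comorbidity ceiling.** The raw "Number of Problems" count enters the
  numerator capped at 18, and the cap of 18 enters the denominator, so
  the diagnosis tally cannot swamp the index.
* **Completeness threshold guard.** No score is issued unless at least
  80 % of the required fields are answered (inclusive at the boundary).
  At or above the threshold, missing items are ignored — they drop out
  of both numerator and denominator.

Scores are reported to four decimal places and always lie in
[0.0000, 1.0000].

Every raw-to-coded mapping lives in a declarative YAML **coding schema**
(a documented default ships with the package and can be exported as a
flat per-value audit table); the engine also enforces field typing,
logical dependencies between fields (answering "No" to *Falls* forces
*Number of Falls* to 0), an all-mandatory demographics page, and
timestamped multi-file CSV record storage with a 3-minute autosave hook.

## A worked example

```python
from eficga import default_schema, Assessment, Demographics, score_assessment
import datetime as dt

schema = default_schema()
a = Assessment(schema=schema, demographics=Demographics(
    healthcare_number="HC12345678", age=81, gender="Female", education="10",
    clinician_id="CL042", assessment_date=dt.date(2026, 9, 26),
    assessment_time=dt.time(10, 30)))
a.set_responses({"cognition": "Mildly Impaired", "cognitive_score": 23,
                 "motivation": "Usual", "falls": "No", "cfs": 4,
                 "number_of_problems": 7, ...: ...})  # every scored item
result = score_assessment(a)
print(f"{result.score:.4f}")
```

Running `python examples/01_score_one_assessment.py` (the full version of
the above) prints:

```
eFI-CGA score : 0.3375
numerator     : 13.5  (sum of coded deficits, comorbidities capped at 18)
denominator   : 40.0  (answered items + the comorbidity cap)
completeness  : 100.0% of required fields answered
items missing : none
```

13.5 deficits out of 40 under evaluation — 22 answered items plus the
comorbidity cap of 18 — give a score of 0.3375, in the moderately frail
range. The other scripts in `examples/` walk through batch scoring with
record persistence, the conformance suite, and authoring a site-specific
schema.

A thin CLI wraps the same library calls:

```
eficga score    --input batch.csv --outdir records/
eficga validate --input batch.csv
eficga simulate --outdir vectors/ --seed 1
eficga schema export --out audit.csv
```

## Conformance testing

`eficga.fixtures` generates four categories of systematic simulation
cases — threshold-guard boundaries (including a fully blank form),
whole-section missingness, value-range extremes, and a sweep covering
every raw value of every item — and scores each with an **independent
oracle**: a separate, deliberately plain transcription of the scoring
rules that shares no code with the engine. The engine must agree with
the oracle on 100 % of cases to four decimal places. `eficga simulate`
exports the suite as input files plus an expected-results table, usable
as conformance vectors for third-party implementations.

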