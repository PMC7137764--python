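"""Batch-score a table of assessments and persist the timestamped records.

Writes a small batch input file, scores it (a too-incomplete row becomes a
refusal row, not an error), saves every encounter to the four CSV record
files plus the text snapshot, and reloads them.
"""

import datetime as dt
import tempfile
from pathlib import Path

from eficga import (
    Assessment,
    ScoreNotComputable,
    default_schema,
    load_records,
    save_records,
    score_assessment,
)
from eficga.fixtures import make_demographics, random_assessment
from eficga.tabular import assessments_to_frame, read_assessments, score_table
import random

schema = default_schema()
rng = random.Random(3)
workdir = Path(tempfile.mkdtemp(prefix="eficga_"))

# three complete encounters plus one with too many blanks to score
assessments = [random_assessment(schema, rng) for _ in range(3)]
assessments.append(random_assessment(schema, rng, answer_fraction=0.5))

batch = workdir / "batch.csv"
assessments_to_frame(assessments, schema).to_csv(batch, index=False)

table = score_table(read_assessments(batch, schema))
print(table[["row", "score", "completeness", "refusal_reason"]].to_string(index=False))
# each row is one patient: a four-decimal score when >= 80 % of required
# fields were answered, otherwise the refusal reason with what is missing

records_dir = workdir / "records"
records_dir.mkdir()
when = dt.datetime(2026, 9, 26, 9, 0, 0)
for i, assessment in enumerate(assessments):
    try:
        result = score_assessment(assessment)
    except ScoreNotComputable as refusal:
        result = refusal
    save_records(assessment, result, records_dir, when=when + dt.timedelta(minutes=3 * i))

print(f"\nrecord files in {records_dir}:")
for f in sorted(records_dir.iterdir()):
    print(f"  {f.name}")

reloaded = load_records(records_dir, schema)
print(f"\nreloaded {len(reloaded)} saved encounters; "
      f"first score on file: {reloaded[0][1].score:.4f}"
      if hasattr(reloaded[0][1], 'score') else "")
# raw_data.csv alone reconstructs each assessment exactly; coded_data.csv
# holds the coded deficits ('none' = missing) and the score for audit
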