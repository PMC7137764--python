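# Methods

## The deficit-accumulation model

The engine computes a Frailty Index (FI) in the Rockwood
deficit-accumulation tradition: frailty is the fraction of evaluated
health deficits that are present,

    eFI-CGA = Σᵢ xᵢ / n,    xᵢ ∈ [0, 1].

Each Comprehensive Geriatric Assessment (CGA) item — cognition, mood,
motivation, senses, sleep, pain, strength, balance, mobility, falls,
function, nutrition, social engagement, medication burden, the Clinical
Frailty Scale, and the comorbidity count — is mapped from its raw
response to a coded deficit value through a declarative coding schema.
Values near 1 indicate greater impairment. The model assumes deficits
are exchangeable (each answered item carries equal weight in the
denominator) and that item codings are monotone in severity; it makes
no distributional assumptions.

Two departures from a plain mean of codings:

* **Comorbidity ceiling.** The raw "Number of Problems" count is added
  to the numerator, capped at `comorbidity_cap` (default 18), while the
  cap — not the answered count — is added to the denominator. This
  prevents a long diagnosis list from dominating the index while still
  letting the count contribute proportionally below the ceiling.
* **Completeness threshold guard.** Scoring is refused when fewer than
  `threshold` (default 0.80) of the required scored items are answered.
  The comparison is inclusive: exactly 80 % computes. At or above the
  threshold, missing items are ignored — excluded from both numerator
  and denominator — rather than imputed.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `comorbidity_cap` | 18 | ceiling on the comorbidity count's numerator contribution; also the fixed denominator share of that item |
| `threshold` | 0.80 | minimum answered fraction of required scored items (inclusive) |
| per-item `coding_map` | 0 / 0.5 / 1 | raw→deficit mapping; ordinal items use three levels, integer items ordered bands |
| autosave `interval` | 180 s | cadence of the caller-owned periodic save hook |

The default schema carries 23 required scored items (22 coded items plus
the comorbidity count) and one optional free-text field. Ordinal items
default to the three-level 0/0.5/1 coding (the Motivation item's stated
High/Usual/Low mapping generalised to the remaining domains); integer
items (a 0–30 cognitive test score, the 1–9 Clinical Frailty Scale, the
falls count) are coded through ordered cut-point bands. The schema is a
first-class input: sites whose form or coding rules differ declare their
own YAML file and every module follows it.

## Numerical choices

* **Rounding.** Scores are rounded to four decimal places,
  half-away-from-zero (`decimal` arithmetic, not binary-float rounding),
  matching clinical display conventions.
* **Missing values** are a distinguished state, never a sentinel inside
  a response domain, so a blank can never be scored as 0.
* **Missing comorbidity count.** When the comorbidity item itself is
  unanswered but overall completeness still clears the threshold, the
  cap is excluded from the denominator — the same ignore-missing
  treatment every other item receives.
* **Degenerate inputs.** A schema with zero required items scores any
  form as complete; a denominator of zero cannot arise because the
  threshold guard refuses first (with a 0.8 threshold at least one item
  must be answered). Non-integer or out-of-range count inputs are
  rejected at entry, not truncated.
* **Dependency rules** (trigger item, trigger value, target item, forced
  value) are schema data, applied to a fixed point in at most one pass
  per rule; cyclic declarations are rejected when the schema is built.

## Validation and gating semantics

Malformed values and missing demographics are blocking *errors*; missing
optional fields are *warnings*. The demographics page is all-mandatory:
`score_assessment` refuses on an incomplete identification page even
when item completeness clears the 80 % rule, and `check_scoreability`'s
`scoreable` flag is defined to agree exactly with whether the scorer
would refuse — an invariant the test suite checks on generated fixtures.
Completeness counts only required scored items (including the comorbidity
count); free-text and other non-scored fields are excluded from the
denominator.

## Storage dialect

Each save appends one row per file — raw TRUE/FALSE choice columns (plus
verbatim integer/text columns), coded values with `none` for missing,
follow-up actions as `Action Required`/`N/A`, a text actions summary,
and a plain-text snapshot of the full form state (serving the recovery
role a form screenshot would, in a headless artifact). All rows of one
save share a date/time stamp and bundle id; files are UTF-8,
comma-separated, header-keyed (column order never carries meaning on
load, and a header that does not match the schema layout is an explicit
error). Saves are staged to temporary files and committed together, so
a failure never leaves a partial bundle; a lock file turns concurrent
writers into an explicit busy error. The score, when issued, is written
to both the raw and the coded table.

## The simulation suite and its oracle

`generate_cases` produces four categories of systematic cases, each
ground-truthed by `oracle_score` — a separate straight-line transcription
of the rules that shares no code with the scoring module:

* `threshold_guard` — a fully blank form, just-below, exactly-at and
  just-above the threshold, then random completeness levels. The
  generator steers around dependency rules so the answered count is
  exactly the one targeted.
* `section_missing` — whole named sections blanked while overall
  completeness stays at or above the threshold (the default schema's
  sections are sized so this is possible).
* `value_range` — all-minimum, all-maximum and all-mid codings, then
  random mixes of the three extremes. Two-level items have no 0.5
  coding, so the mid case is predominantly, not uniformly, 0.5.
* `mapping_sweep` — items cycle through their response domains across
  cases until every raw value of every item has appeared at least once;
  an item whose value was overwritten by a dependency rule retries in a
  later case, so `count` is a minimum, not an exact size.

The default suite size is 8 cases per category; the sweep category grows
to whatever coverage requires (60 cases for the default schema, giving
84 in total). Generation is deterministic given the seed.

What the generator does **not** emulate: real patients. Responses are
drawn uniformly or by construction, item values are independent, and no
clinical correlation structure (e.g. between mobility items and falls)
is modelled. Passing the suite demonstrates arithmetic and rule
conformance of the calculator — coding, capping, guarding, rounding —
not clinical validity of the scores on any population; cohort-level
statistics computed on generated data are meaningless by design.

## Problem sizes

The shipped tests exercise: exhaustive enumeration of all 3⁶ outcomes on
a six-item schema (oracle monotonicity) and 3⁴ × 4 on a four-item schema
(bounds), a 21-point completeness sweep on a 20-item schema, the
84-case four-category suite, and 10,000 random assessments against the
oracle — sizes chosen so the whole suite runs in seconds while every
rule boundary (cap, threshold, rounding half) is hit exactly.

## Known limitations

* The default schema is a documented, faithful-where-stated default, not
  a reproduction of any particular site's full coding table; deployments
  are expected to audit and, where needed, replace it.
* One dependency rule ships by default (Falls → Number of Falls); real
  forms typically carry more, which sites add as schema data.
* Storage is local plain-text CSV by design (no encryption, no server);
  confidentiality is the deployment's responsibility.
* The autosave is a hook, not a timer: headless callers own the clock
  and call `tick()`.
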