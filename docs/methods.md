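# Methods

## The phenotype model

The packaged model (`src/gmfpm/data/gmfpm_model.yaml`, schema in
`src/gmfpm/data/model_definition.schema.json`) is a rules-as-data document:
20 variables over 65 data element concepts in 5 domains, for patients aged
6–18 (inclusive completed years — the widest GMFCS age band, over which
levels are stable). A *unique* variable wraps one data element concept; a
*derived* variable consolidates several concepts sharing one value-set
structure (e.g. the three tone variables each combine a flexor and an
extensor Modified Ashworth Scale element; Feeding Ability combines nine
yes/no elements). OMOP custom concept codes are carried where published
(the 19 Activity Performance codes); all other elements are matched by
canonical name, with codes addable through the definition document.

Every variable carries one logic statement per GMF class: a human-readable
stem/rule/qualifier triple plus a machine predicate of one of three kinds —
token **membership** (unique and derived-ordinal variables; for derived
binary variables the tokens are element names matched against positively
observed elements, mirroring how the published matrices list element names
as class values), **count thresholds** over binary elements (eq/ge/le a
count of "Yes"), and **all-of** (every element carries a token, used for
"No treatments"). Each statement records provenance: `paper` where the
predicate transcribes published rule content (the Activity Performance
matrix and the Elbow Tone MAS gradation), `default` where this package
supplies a clinically monotone default (the remaining variables, including
Knee/Ankle Tone which mirror the Elbow gradation since they share the MAS
construct, and Ambulation Level, whose published statement is only
available as a figure). Defaults are overridable by editing the definition
document; they are design choices of this package, not published content.

Value-set canonicalization is trim + case-insensitive match against
canonical tokens, then aliases; the MAS value set is ordered
0 < 1 < 1.5 < 2 < 3 < 4 with "1+"/"+1" as aliases of "1.5".

## Rule evaluation and class assignment

Statement evaluation is tri-state: `missing` iff the variable resolved to
no value (no element observed in-window, or only conflicted elements);
otherwise `match`/`no_match`. Under the default **closed-world** flag,
unobserved binary elements inside a *partially* observed derived variable
count as "No" — EHR checklists record positives — while a wholly
unobserved variable stays missing; with the flag off, partially observed
count/all-of predicates return missing instead. Derived ordinal variables
resolve to the most severe observed element value before membership
evaluation (a single per-class gradation is published per tone variable,
not per element).

Class value sets overlap by design (they absorb within-class variation), so
a variable's value can satisfy several classes. The combination of the 20
per-variable memberships into one patient-level class is not part of the
published model; the engine therefore makes the resolution policy explicit
and pluggable. The default, `proportion_argmax`, scores each class by the
fraction of evaluated variables matching it and assigns the argmax;
ties at the maximum and coverage below `min_coverage` (default 5 evaluated
variables) yield an explicit `INDETERMINATE` with the tied classes reported
— never an arbitrary tie-break. "Any one treatment" is read as ≥ 1 and
"concerns with any one fine motor activity" as exactly 1, keeping the
Class 2/Class 3 fine-motor predicates disjoint against Class 3's "more
than one"; both readings are configurable in the definition document.

## OMOP adapter

Inputs are delimited text (comma default, tab accepted) with mandatory
headers: `person_id, birth_date` and `person_id, concept_code,
concept_name, value, observation_date`, ISO-8601 dates at calendar-day
granularity. Malformed rows are rejected with row numbers, never silently
dropped; a missing column is fatal. Concept matching prefers the numeric
code and falls back to exact canonical element name. Per element, the most
recent observation in `[index_date − window_days, index_date]` wins
(default window 365 days — year-scale is safe given GMFCS stability);
distinct same-day values are a documentation conflict, logged, and the
element treated as unobserved. Every person is exactly one of: age-excluded
(outside 6–18 at index), emitted with features, or emitted with all
variables missing (counted separately).

## Expert-panel consensus builder

The builder reconstructs the model-construction methodology itself: a
registry of candidate variables (the packaged fixture has 31 = 14 unique +
17 derived, hence 93 EX1 cells per panelist) is aggregated per
(variable, class) by token votes among responding panelists — single modal
token with strict majority → consensus; exactly two modal tokens (a 2–2
tie, or shared multi-value assignments) → both; otherwise the union of all
assigned tokens. Inclusion from EX2 ratings excludes declined ratings from
the denominator: strict majority ≥ 3 includes, an exact even split across
the 2/3 boundary includes as a split, strict majority ≤ 2 excludes.
"Consensus" is read as strict majority — the weakest reading under which
the 2–2 split is a distinct case. Conformance retains a variable only when
its aggregated per-class sets are not all identical *and* the rating
decision included it; named overrides retain a non-conformant variable
with an audit trail entry. Merges are explicit directives (the negation-
phrased variables folded into their positive counterparts), never
inferred. The audit covers every registry variable exactly once, and
aggregation is permutation-invariant over panelists.

The fixture under `src/gmfpm/data/panel/` is **synthetic**: it is
reverse-engineered to reproduce the reported outcomes (one conformance
drop for a general lower-extremity tone variable whose values were
identical in all classes; Elbow Tone excluded on ratings {2, 2, declined,
3} and retained only by domain-expert override; three merges; 20 final
variables), not a record of any real panel's responses. The seven
additional rating-excluded variables are inventions needed to fill the
31-variable registry.

## Synthetic cohorts and recovery

The simulator emulates class-conditional flowsheet documentation: per
patient a true GMFCS level is drawn from `class_mix` (default uniform over
the five levels), age uniform over 6–18, observation dates uniform over a
one-year `date_range` whose end is the index date. Per non-missing
variable, with probability `fidelity` the value is drawn from the true
class's admissible set — a uniform admissible token for membership
predicates, one positive element for element-name memberships, a uniform
satisfying count with random positive positions for count predicates — and
with probability 1 − `fidelity` uniformly from the non-admissible
remainder (classes whose admissible set spans the whole value set cannot
produce off-class draws). Derived binary variables are emitted with
explicit "Yes"/"No" rows for every element; `conflict_rate` injects
same-day contradictory duplicates that the adapter resolves to missing.
Defaults (n=300 patients, fidelity 0.95, missingness 0.10,
conflict_rate 0) are the package's study conditions; n=300 runs the full
simulate→extract→assign→score loop in seconds on one CPU.

What the generator does *not* emulate: severity-adjacent confusion
(off-class draws are uniform, not biased toward neighbouring classes),
realistic visit scheduling, longitudinal change, correlated missingness,
or true class-conditional value frequencies from any real network —
uniform-within-admissible is a declared stand-in. Passing recovery tests
therefore show that the pipeline inverts its own generative model under
noise, not that real EHR data would classify this well.

Recovery is scored as a 3×3 confusion matrix with an explicit
`INDETERMINATE` column; accuracy is computed among determinate assignments
only (forced choice would mask ties) and reported as not-applicable when
everything is indeterminate. A 50-replicate pilot at the default
conditions (n=300, fidelity 0.95, missingness 0.1, seeds 0–49) observed
determinate accuracy min 0.9967 / mean 0.9999; the regression bound in the
test suite is frozen at 0.95. Mean accuracy is monotone in fidelity over
{1.0, 0.9, 0.7, 0.5} (pilot means 1.0 / 0.997 / 0.824 / 0.318). At
fidelity 1.0 and no missingness recovery is exact: every class pair is
separated by at least one deterministic discriminator (e.g. Current Home
Treatments separates Classes 2/3; the count-based concern variables
separate Class 1), and `class_value_overlap` itemizes the variables that
cannot separate a given pair on their own.

## Numerical and degenerate-input choices

- Ties are reported, never broken by order or chance.
- Zero evaluated variables → `INDETERMINATE` with scores 0, never an
  exception; an empty model definition is valid with a warning.
- Duplicate concept codes, unknown value-set references, unknown membership
  tokens and missing per-class statements are validation errors collected
  into a report listing every offending path.
- Completed-years age with inclusive band endpoints; dates are calendar
  days, so same-day observations are unordered (conflicts, not recency).
- All randomness flows from a single integer seed through one numpy
  generator; identical seeds give byte-identical output tables.

## Known limitations

- Rules marked `default` (12 of 20 variables) are this package's monotone
  clinical defaults, not published content; conclusions about those
  variables' discriminative value reflect the defaults.
- The resolution policy is a package choice; the published model defines
  per-variable membership only.
- The adapter handles only the observation columns above — no visit/era
  logic, no coded-value (concept-id) values, no database connectivity.
- The consensus fixture is synthetic (above); inter-rater statistics
  (e.g. kappa) are out of scope.
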