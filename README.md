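# gmfpm — computable phenotyping of gross motor function

Children with cerebral palsy are routinely classified on the Gross Motor
Function Classification System (GMFCS), a five-level ordinal scale (I least
to V most limited). In electronic health records the GMFCS level is rarely a
discrete field — it hides in free-text notes — which makes cohort
identification by functional level hard. `gmfpm` implements a **phenotype
model** answer to that problem: a declarative specification of 20 variables
built from 65 standardized OMOP data element concepts across five
performance-related domains (Neurologic Function, Mobility Performance,
Activity Performance, Motor Performance, Device Use), each variable carrying
class-stratified logic statements that instantiate membership in one of
three clinically meaningful **GMF classes** — the collapse of GMFCS
I–II → Class 1 (ambulates without assistive devices), III → Class 2
(assistive-device users), IV–V → Class 3 (significant ambulatory
limitation) — for patients aged 6–18.

The package provides, as importable modules and a thin CLI:

- **`gmfpm.model`** — the declarative model (value sets, data element
  concepts with OMOP custom codes such as `2500010257` for respiratory
  support, variables, logic statements) loaded from a versioned YAML
  document and validated against published invariants.
- **`gmfpm.rules`** — tri-state evaluation (match / no-match / missing) of
  each class-stratified predicate, e.g. the Modified Ashworth Scale tone
  gradation *Class 1: {0, 1, 1+} · Class 2: {1, 1+, 2, 3} ·
  Class 3: {2, 3, 4}*, and a pluggable resolution policy
  (default: proportion-argmax over evaluated variables, with explicit
  `INDETERMINATE` for ties and low coverage).
- **`gmfpm.omop`** — ingestion of delimited OMOP-style person/observation
  tables, age-band scoping, look-back window with recency resolution and
  same-day-conflict handling.
- **`gmfpm.consensus`** — the expert-panel methodology used to construct
  such models: EX1 value aggregation (consensus / tie / union rules), EX2
  rating-based inclusion (strict majority ≥ 3, even splits, exclusions),
  the conformance audit, variable merges, and model emission.
- **`gmfpm.simulate`** — a synthetic cohort generator with known GMFCS
  truth (configurable fidelity, missingness, documentation conflicts) and
  recovery scoring with an explicit indeterminate column.

## Worked example

`examples/` contains one narrative script per capability. Classifying a
three-patient cohort (`python examples/02_classify_cohort.py`) prints:

```
person_id  score_class1  score_class2  score_class3  n_evaluated  n_missing      assigned tied_classes            policy model_version
       P1           0.0      0.166667           1.0            6         14             3              proportion_argmax           1.0
       P2           1.0      0.200000           0.0            5         15             1              proportion_argmax           1.0
       P3           1.0      1.000000           0.0            5         15 INDETERMINATE          1;2 proportion_argmax           1.0
```

Each score is the fraction of that patient's *evaluated* variables whose
value satisfies the class's logic statement (missing variables carry no
vote). P1 — MAS tone 4, dependent ambulation, tube feeding — satisfies
every evaluated Class 3 rule. P3's observations all sit in the published
Class 1/2 overlap (MAS 1/1+, intact sitting balance, toilet trained), so
both classes score 1.0 and the engine reports the tie as `INDETERMINATE`
rather than breaking it arbitrarily — ties are clinically meaningful
output, not noise.

Simulating 300 patients at documentation fidelity 0.95 with 10% missingness
(`python examples/04_simulate_and_recover.py`) recovers the true class with
determinate accuracy 1.0000 and indeterminate rate 0.0000, and itemizes
the variables whose class value sets are identical for some class pair
(e.g. Current Home Treatments, whose Class 1 and Class 2 rules are both
"No treatments") — those variables cannot separate that pair on their own.

The same pipelines are available from the shell:

```bash
gmfpm validate-model
gmfpm simulate --n 300 --seed 7 --out-dir sim/
gmfpm classify --persons sim/persons.csv --observations sim/observations.csv \
               --index-date 2024-12-31 --out-dir out/
gmfpm evaluate --assignments out/assignments.csv --truth sim/truth.csv
gmfpm build-model --out-dir built/   # panel-consensus pipeline on the packaged fixture
```

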