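"""Class-stratified rule evaluation and GMF class assignment.

Each model variable carries one logic statement per GMF class; a statement's
predicate is evaluated against a patient's resolved feature vector to a
tri-state result (match / no-match / missing).  A variable's value may
legitimately satisfy the statements of several classes — the published value
sets overlap by design to absorb within-class variation — so per-variable
results are set-valued and a pluggable resolution policy combines them into a
single class assignment (or an explicit INDETERMINATE).
"""

from __future__ import annotations

import enum
from typing import Iterable, Literal, Sequence, Union

import pandas as pd
from pydantic import BaseModel, Field

from .model import (
    GmfClass,
    LogicStatement,
    PhenotypeModel,
    ValuePredicate,
    Variable,
)
from .omop import PatientFeatureVector

__all__ = [
    "TriState",
    "VariableMatch",
    "ClassAssignment",
    "INDETERMINATE",
    "ConfigurationError",
    "evaluate_statement",
    "match_classes_for_variable",
    "assign_class",
    "assign_cohort",
    "assignments_to_frame",
    "class_value_overlap",
]

#: Sentinel used in ``ClassAssignment.assigned`` when no single class wins.
INDETERMINATE = "INDETERMINATE"

#: Default minimum number of evaluated variables required for a determinate
#: assignment under the proportion-argmax policy.
DEFAULT_MIN_COVERAGE = 5


class TriState(str, enum.Enum):
    MATCH = "match"
    NO_MATCH = "no_match"
    MISSING = "missing"


class ConfigurationError(RuntimeError):
    """Model/engine configuration is inconsistent (e.g. a variable without
    statements that is not marked rule-incomplete)."""


class VariableMatch(BaseModel):
    variable: str
    matched_classes: set[GmfClass] = Field(default_factory=set)
    status: Literal["evaluated", "missing"] = "evaluated"


class ClassAssignment(BaseModel):
    """Resolved assignment for one patient.

    ``per_class_score`` are fractions of *evaluated* variables whose value
    satisfied each class's statement; missing variables carry no vote.
    """

    person_id: str
    per_class_score: dict[GmfClass, float]
    n_evaluated: int
    n_missing: int
    assigned: Union[GmfClass, str]
    tied_classes: set[GmfClass] = Field(default_factory=set)
    policy: str = "proportion_argmax"

    @property
    def is_determinate(self) -> bool:
        return self.assigned != INDETERMINATE


def _positive_elements(value: dict, positive: str = "Yes") -> set[str]:
    return {el for el, tok in value.items() if tok == positive}


def evaluate_statement(
    statement: LogicStatement,
    features: PatientFeatureVector,
    model: PhenotypeModel,
    closed_world: bool = True,
) -> TriState:
    """Evaluate one logic statement against one patient.

    Returns MISSING iff the variable is unresolved (no underlying element
    observed, or resolved to a conflict).  With ``closed_world`` on
    (default), unobserved binary elements inside a *partially* observed
    derived variable are treated as "No" — EHR checklists record positives;
    with it off, partially observed count/all-of predicates are MISSING.
    """
    var = model.variable_by_name(statement.variable)
    if var.name in features.missing_variables:
        return TriState.MISSING
    value = features.values.get(var.name)
    if value is None or (isinstance(value, dict) and not value):
        return TriState.MISSING

    vs = model.value_set_by_name(var.value_set)
    pred = statement.predicate

    if pred.kind == "membership":
        tokens = set(pred.tokens or [])
        if isinstance(value, str):
            if value not in vs.values:
                raise ValueError(
                    f"token {value!r} outside value set {vs.name!r} reached the "
                    "engine; canonicalize inputs first"
                )
            return TriState.MATCH if value in tokens else TriState.NO_MATCH
        # Derived binary: tokens are element names; match on any positive.
        positives = _positive_elements(value)
        return TriState.MATCH if positives & tokens else TriState.NO_MATCH

    if not isinstance(value, dict):
        raise ValueError(
            f"{pred.kind} predicate on {var.name!r} requires per-element values"
        )
    fully_observed = len(value) == len(var.elements)
    if not closed_world and not fully_observed:
        return TriState.MISSING

    if pred.kind == "count_threshold":
        count = sum(1 for tok in value.values() if tok == pred.positive_token)
        k = int(pred.k or 0)
        ok = {"eq": count == k, "ge": count >= k, "le": count <= k}[pred.comparator]
        return TriState.MATCH if ok else TriState.NO_MATCH

    # all_of: unobserved elements impute to "No" under closed world.
    observed_ok = all(tok == pred.token for tok in value.values())
    imputed_ok = fully_observed or pred.token == "No"
    return TriState.MATCH if observed_ok and imputed_ok else TriState.NO_MATCH


def match_classes_for_variable(
    variable: Variable,
    features: PatientFeatureVector,
    model: PhenotypeModel,
    closed_world: bool = True,
) -> VariableMatch:
    """All GMF classes whose statement the patient's value satisfies."""
    statements = model.statements_for(variable.name)
    if not statements:
        if variable.rule_incomplete:
            return VariableMatch(variable=variable.name, status="missing")
        raise ConfigurationError(
            f"variable {variable.name!r} has no statements and is not marked "
            "rule-incomplete"
        )
    matched: set[GmfClass] = set()
    any_evaluated = False
    for st in statements:
        res = evaluate_statement(st, features, model, closed_world=closed_world)
        if res is not TriState.MISSING:
            any_evaluated = True
        if res is TriState.MATCH:
            matched.add(st.gmf_class)
    if not any_evaluated:
        return VariableMatch(variable=variable.name, status="missing")
    return VariableMatch(variable=variable.name, matched_classes=matched, status="evaluated")


def assign_class(
    model: PhenotypeModel,
    features: PatientFeatureVector,
    policy: str = "proportion_argmax",
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    closed_world: bool = True,
) -> ClassAssignment:
    """Resolve per-variable matches into one GMF class (or INDETERMINATE).

    Default policy ``proportion_argmax``: score(c) = (# evaluated variables
    matching c) / (# evaluated variables); the argmax wins.  Ties at the
    maximum, or fewer than ``min_coverage`` evaluated variables, yield
    INDETERMINATE — ties are reported, never broken arbitrarily.
    """
    if policy != "proportion_argmax":
        raise ConfigurationError(f"unknown resolution policy {policy!r}")
    n_evaluated = 0
    n_missing = 0
    counts = {c: 0 for c in GmfClass}
    for var in model.variables:
        vm = match_classes_for_variable(var, features, model, closed_world=closed_world)
        if vm.status == "missing":
            n_missing += 1
            continue
        n_evaluated += 1
        for c in vm.matched_classes:
            counts[c] += 1
    scores = {
        c: (counts[c] / n_evaluated if n_evaluated else 0.0) for c in GmfClass
    }
    if n_evaluated < min_coverage:
        return ClassAssignment(
            person_id=features.person_id,
            per_class_score=scores,
            n_evaluated=n_evaluated,
            n_missing=n_missing,
            assigned=INDETERMINATE,
            tied_classes=set(),
            policy=policy,
        )
    top = max(scores.values())
    winners = {c for c, s in scores.items() if s == top}
    if len(winners) == 1:
        assigned: Union[GmfClass, str] = next(iter(winners))
        tied: set[GmfClass] = set()
    else:
        assigned = INDETERMINATE
        tied = winners
    return ClassAssignment(
        person_id=features.person_id,
        per_class_score=scores,
        n_evaluated=n_evaluated,
        n_missing=n_missing,
        assigned=assigned,
        tied_classes=tied,
        policy=policy,
    )


def assign_cohort(
    model: PhenotypeModel,
    feature_vectors: Iterable[PatientFeatureVector],
    policy: str = "proportion_argmax",
    min_coverage: int = DEFAULT_MIN_COVERAGE,
    closed_world: bool = True,
) -> list[ClassAssignment]:
    return [
        assign_class(model, fv, policy=policy, min_coverage=min_coverage, closed_world=closed_world)
        for fv in feature_vectors
    ]


def assignments_to_frame(
    assignments: Sequence[ClassAssignment], model_version: str = ""
) -> pd.DataFrame:
    """Tabular assignment output (one row per patient)."""
    rows = []
    for a in assignments:
        rows.append(
            {
                "person_id": a.person_id,
                "score_class1": a.per_class_score[GmfClass.C1],
                "score_class2": a.per_class_score[GmfClass.C2],
                "score_class3": a.per_class_score[GmfClass.C3],
                "n_evaluated": a.n_evaluated,
                "n_missing": a.n_missing,
                "assigned": str(int(a.assigned)) if a.is_determinate else INDETERMINATE,
                "tied_classes": ";".join(str(int(c)) for c in sorted(a.tied_classes)),
                "policy": a.policy,
                "model_version": model_version,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "person_id",
            "score_class1",
            "score_class2",
            "score_class3",
            "n_evaluated",
            "n_missing",
            "assigned",
            "tied_classes",
            "policy",
            "model_version",
        ],
    )


# ---------------------------------------------------------------------------
# Class-overlap itemization
# ---------------------------------------------------------------------------

def enumerate_variable_outcomes(variable: Variable, model: PhenotypeModel):
    """Every fully observed resolved value a variable can take.

    Tokens for unique / derived-ordinal variables; for derived binary
    variables, every assignment of Yes/No over the elements (2^n outcomes,
    n <= 12 in the packaged model).
    """
    vs = model.value_set_by_name(variable.value_set)
    if variable.kind == "unique" or vs.kind != "binary":
        return list(vs.values)
    out = []
    names = [e.name for e in variable.elements]
    for mask in range(2 ** len(names)):
        out.append({n: ("Yes" if mask >> i & 1 else "No") for i, n in enumerate(names)})
    return out


def _satisfies(pred: ValuePredicate, outcome, variable: Variable) -> bool:
    if pred.kind == "membership":
        toks = set(pred.tokens or [])
        if isinstance(outcome, str):
            return outcome in toks
        return bool(_positive_elements(outcome) & toks)
    count = sum(1 for t in outcome.values() if t == (pred.positive_token or pred.token))
    if pred.kind == "count_threshold":
        k = int(pred.k or 0)
        return {"eq": count == k, "ge": count >= k, "le": count <= k}[pred.comparator]
    return all(t == pred.token for t in outcome.values())


def class_value_overlap(model: PhenotypeModel) -> pd.DataFrame:
    """Itemize, per variable, which class pairs share satisfying values.

    Overlapping class value sets are intentional in the published rules
    (they absorb within-class variation) but bound what perfect-fidelity
    classification can discriminate; one row per variable with the
    overlapping and identical class pairs.
    """
    rows = []
    for var in model.variables:
        outcomes = enumerate_variable_outcomes(var, model)
        sat = {}
        for c in GmfClass:
            stmts = model.statements_for(var.name, c)
            sat[c] = {
                i
                for i, o in enumerate(outcomes)
                if any(_satisfies(s.predicate, o, var) for s in stmts)
            }
        overlapping, identical = [], []
        for a, b in ((GmfClass.C1, GmfClass.C2), (GmfClass.C1, GmfClass.C3), (GmfClass.C2, GmfClass.C3)):
            if sat[a] & sat[b]:
                overlapping.append(f"{int(a)}-{int(b)}")
            if sat[a] == sat[b] and sat[a]:
                identical.append(f"{int(a)}-{int(b)}")
        rows.append(
            {
                "variable": var.name,
                "overlapping_pairs": ";".join(overlapping),
                "identical_pairs": ";".join(identical),
            }
        )
    return pd.DataFrame(rows, columns=["variable", "overlapping_pairs", "identical_pairs"])
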