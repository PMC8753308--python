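"""Synthetic cohort generation with known GMFCS truth, and recovery scoring.

The generator emulates class-conditional flowsheet documentation over the
model's value sets: each simulated patient has a true GMFCS level (hence a
true GMF class); each non-missing variable's value is drawn from the true
class's admissible set with probability ``fidelity`` and otherwise uniformly
from the non-admissible remainder, the simplest null noise model.  Per-
variable missingness and same-day contradictory duplicates (documentation
conflicts) are injected at configurable rates.  Output uses exactly the
delimited person/observation formats the adapter reads, so simulate ->
extract -> assign exercises the full pipeline.
"""

from __future__ import annotations

import datetime as dt
import warnings
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator, model_validator

from .model import (
    GmfClass,
    GmfcsLevel,
    PhenotypeModel,
    ValuePredicate,
    Variable,
    collapse_gmfcs,
)
from .rules import ClassAssignment, INDETERMINATE

__all__ = [
    "SimulationConfig",
    "TruthLabel",
    "SimulatedCohort",
    "RecoveryReport",
    "simulate_cohort",
    "evaluate_recovery",
]


class SimulationConfig(BaseModel):
    """Study conditions for one simulated cohort.

    ``fidelity`` is the probability that a generated variable value lies in
    the patient's true-class admissible set; ``missingness`` (scalar or
    per-variable map) the probability a variable goes unobserved;
    ``conflict_rate`` the per-element probability of an extra same-day
    contradictory record.  Ages are uniform over the model age band,
    observation dates uniform over ``date_range``.
    """

    n_patients: int = 300
    class_mix: dict[str, float] = Field(
        default_factory=lambda: {lvl.name: 0.2 for lvl in GmfcsLevel}
    )
    fidelity: float = 0.95
    missingness: Union[float, dict[str, float]] = 0.1
    conflict_rate: float = 0.0
    seed: int = 0
    date_range: tuple[dt.date, dt.date] = (dt.date(2024, 1, 1), dt.date(2024, 12, 31))

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if abs(sum(self.class_mix.values()) - 1.0) > 1e-9:
            raise ValueError("class_mix proportions must sum to 1")
        for lvl in self.class_mix:
            GmfcsLevel.parse(lvl)
        probs = [self.fidelity, self.conflict_rate]
        probs += (
            list(self.missingness.values())
            if isinstance(self.missingness, dict)
            else [self.missingness]
        )
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.date_range[0] > self.date_range[1]:
            raise ValueError("date_range start must not follow end")
        return self

    def missingness_for(self, variable: str) -> float:
        if isinstance(self.missingness, dict):
            return self.missingness.get(variable, 0.0)
        return self.missingness


class TruthLabel(BaseModel):
    person_id: str
    true_gmfcs: GmfcsLevel
    true_class: GmfClass

    @field_validator("true_gmfcs", mode="before")
    @classmethod
    def _parse_level(cls, v):
        return GmfcsLevel.parse(v)

    @model_validator(mode="after")
    def _check(self) -> "TruthLabel":
        if self.true_class != collapse_gmfcs(self.true_gmfcs):
            raise ValueError("true_class must equal collapse_gmfcs(true_gmfcs)")
        return self


class SimulatedCohort(BaseModel):
    persons: object  # pd.DataFrame: person_id, birth_date
    observations: object  # pd.DataFrame: person_id, concept_code, concept_name, value, observation_date
    truth: list[TruthLabel]
    index_date: dt.date

    model_config = {"arbitrary_types_allowed": True}

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "person_id": t.person_id,
                    "true_gmfcs": t.true_gmfcs.name,
                    "true_class": int(t.true_class),
                }
                for t in self.truth
            ]
        )


# ---------------------------------------------------------------------------
# Admissible-set samplers
# ---------------------------------------------------------------------------

def _count_set(pred: ValuePredicate, n: int) -> set[int]:
    """Counts of positive elements satisfying a count/all_of predicate."""
    if pred.kind == "all_of":
        return {0} if pred.token == "No" else {n}
    k = int(pred.k or 0)
    cmp = pred.comparator
    return {c for c in range(n + 1) if {"eq": c == k, "ge": c >= k, "le": c <= k}[cmp]}


def _draw_variable(
    var: Variable,
    pred: ValuePredicate,
    model: PhenotypeModel,
    on_class: bool,
    rng: np.random.Generator,
) -> Union[str, dict[str, str]]:
    """Draw one resolved value for a variable: from the predicate's
    admissible set when ``on_class``, else uniformly from the remainder
    (falling back to the admissible set when the remainder is empty, e.g.
    a class whose membership spans the whole value set)."""
    vs = model.value_set_by_name(var.value_set)
    element_names = [e.name for e in var.elements]
    n = len(element_names)

    if pred.kind == "membership" and (var.kind == "unique" or vs.kind != "binary"):
        admissible = list(pred.tokens or [])
        pool = admissible if on_class else [t for t in vs.values if t not in admissible]
        pool = pool or admissible
        return pool[rng.integers(len(pool))]

    if pred.kind == "membership":  # derived binary: one positive element
        admissible = list(pred.tokens or [])
        pool = admissible if on_class else [e for e in element_names if e not in admissible]
        pool = pool or admissible
        positive = pool[rng.integers(len(pool))]
        return {e: ("Yes" if e == positive else "No") for e in element_names}

    counts = sorted(_count_set(pred, n))
    pool_counts = (
        counts if on_class else sorted(set(range(n + 1)) - set(counts))
    ) or counts
    count = pool_counts[rng.integers(len(pool_counts))]
    chosen = set(rng.choice(n, size=count, replace=False)) if count else set()
    return {e: ("Yes" if i in chosen else "No") for i, e in enumerate(element_names)}


def _flip_token(token: str, values: Sequence[str], rng: np.random.Generator) -> str:
    others = [v for v in values if v != token]
    return others[rng.integers(len(others))] if others else token


def simulate_cohort(model: PhenotypeModel, config: SimulationConfig) -> SimulatedCohort:
    """Generate persons, observation records and truth labels.

    Fully reproducible from ``config.seed``; the index date implied for
    downstream extraction is ``config.date_range[1]``.
    """
    rng = np.random.default_rng(config.seed)
    start, end = config.date_range
    span = (end - start).days
    index_date = end

    levels = sorted(config.class_mix, key=lambda s: GmfcsLevel.parse(s))
    weights = np.array([config.class_mix[k] for k in levels], dtype=float)
    weights = weights / weights.sum()

    simulable = [v for v in model.variables if model.statements_for(v.name)]
    for v in model.variables:
        if not model.statements_for(v.name):
            warnings.warn(f"variable {v.name!r} has no rules; skipped in simulation")

    lo, hi = model.age_band
    persons_rows, obs_rows, truth = [], [], []
    for i in range(config.n_patients):
        pid = f"P{i:05d}"
        level = GmfcsLevel.parse(levels[rng.choice(len(levels), p=weights)])
        true_class = collapse_gmfcs(level)
        age = int(rng.integers(lo, hi + 1))
        birth = index_date.replace(year=index_date.year - age) - dt.timedelta(
            days=int(rng.integers(0, 365))
        )
        persons_rows.append({"person_id": pid, "birth_date": birth.isoformat()})
        truth.append(TruthLabel(person_id=pid, true_gmfcs=level, true_class=true_class))

        for var in simulable:
            if rng.random() < config.missingness_for(var.name):
                continue
            statements = model.statements_for(var.name, true_class)
            if not statements:
                continue
            pred = statements[rng.integers(len(statements))].predicate
            on_class = bool(rng.random() < config.fidelity)
            value = _draw_variable(var, pred, model, on_class, rng)
            date = (start + dt.timedelta(days=int(rng.integers(0, span + 1)))).isoformat()
            vs = model.value_set_by_name(var.value_set)
            if isinstance(value, str):
                per_element = {e.name: value for e in var.elements}
            else:
                per_element = value
            for el in var.elements:
                token = per_element[el.name]
                row = {
                    "person_id": pid,
                    "concept_code": el.concept_code if el.concept_code is not None else "",
                    "concept_name": el.name,
                    "value": token,
                    "observation_date": date,
                }
                obs_rows.append(row)
                if rng.random() < config.conflict_rate:
                    dup = dict(row, value=_flip_token(token, vs.values, rng))
                    obs_rows.append(dup)

    persons = pd.DataFrame(persons_rows, columns=["person_id", "birth_date"])
    observations = pd.DataFrame(
        obs_rows,
        columns=["person_id", "concept_code", "concept_name", "value", "observation_date"],
    )
    return SimulatedCohort(
        persons=persons, observations=observations, truth=truth, index_date=index_date
    )


# ---------------------------------------------------------------------------
# Recovery evaluation
# ---------------------------------------------------------------------------

class RecoveryReport(BaseModel):
    """Confusion of assigned vs true GMF class with INDETERMINATE explicit.

    ``accuracy`` is computed among determinate assignments only (forced
    choice would mask ties); None when every assignment is indeterminate.
    """

    confusion: dict[int, dict[str, int]]
    n_patients: int
    accuracy: Optional[float]
    indeterminate_rate: float
    per_class_sensitivity: dict[int, Optional[float]]

    def confusion_frame(self) -> pd.DataFrame:
        cols = ["1", "2", "3", INDETERMINATE]
        df = pd.DataFrame(self.confusion).T.reindex(columns=cols)
        df.index.name = "true_class"
        return df

    def to_text(self) -> str:
        lines = [self.confusion_frame().to_string()]
        acc = "not applicable" if self.accuracy is None else f"{self.accuracy:.4f}"
        lines.append(f"determinate accuracy: {acc}")
        lines.append(f"indeterminate rate:   {self.indeterminate_rate:.4f}")
        for c in (1, 2, 3):
            s = self.per_class_sensitivity[c]
            lines.append(
                f"class {c} sensitivity: " + ("not applicable" if s is None else f"{s:.4f}")
            )
        return "\n".join(lines)


def evaluate_recovery(
    assignments: Sequence[ClassAssignment], truth: Sequence[TruthLabel]
) -> RecoveryReport:
    """Score assignments against truth labels (person_id sets must match)."""
    a_ids = {a.person_id for a in assignments}
    t_ids = {t.person_id for t in truth}
    if a_ids != t_ids:
        raise ValueError(
            f"person_id mismatch; only-in-assignments={sorted(a_ids - t_ids)[:5]}, "
            f"only-in-truth={sorted(t_ids - a_ids)[:5]}"
        )
    truth_by_id = {t.person_id: t for t in truth}
    confusion = {c: {"1": 0, "2": 0, "3": 0, INDETERMINATE: 0} for c in (1, 2, 3)}
    n_det = n_correct = n_ind = 0
    det_by_class = {c: [0, 0] for c in (1, 2, 3)}  # [correct, determinate]
    for a in assignments:
        t = truth_by_id[a.person_id]
        tc = int(t.true_class)
        if a.is_determinate:
            ac = int(a.assigned)
            confusion[tc][str(ac)] += 1
            n_det += 1
            det_by_class[tc][1] += 1
            if ac == tc:
                n_correct += 1
                det_by_class[tc][0] += 1
        else:
            confusion[tc][INDETERMINATE] += 1
            n_ind += 1
    n = len(assignments)
    return RecoveryReport(
        confusion=confusion,
        n_patients=n,
        accuracy=(n_correct / n_det) if n_det else None,
        indeterminate_rate=n_ind / n if n else 0.0,
        per_class_sensitivity={
            c: (det_by_class[c][0] / det_by_class[c][1]) if det_by_class[c][1] else None
            for c in (1, 2, 3)
        },
    )
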