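"""Expert-panel aggregation and conformance audit.

Implements the two-exercise panel methodology used to construct the
phenotype model.  A registry of candidate variables (unique and derived) is
put before a small expert panel; in exercise EX1 each panelist assigns, per
GMF class, the value(s) of each variable they expect for patients of that
class (one cell per variable x class); in EX2 each panelist rates on a
1..5 scale how well the variable distinguishes the three classes (panelists
may decline).

Aggregation of EX1 per cell: (a) a strict majority of responding panelists
behind a single modal value -> that value; (b) exactly two modal values
(a tie, or multi-value assignments producing two modes) -> both; (c)
otherwise -> the union of all assigned values.  Inclusion from EX2: strict
majority of non-declined ratings >= 3 -> include; an exact even split across
the 2/3 boundary -> include as split; strict majority <= 2 -> exclude.
Conformance retains a variable only when its aggregated per-class value
sets are not all identical *and* the rating decision included it; named
overrides may retain a non-conformant variable with an audit note.

The packaged fixture under ``data/panel/`` is synthetic: a reconstruction
of the published panel outcomes (31-variable registry, one conformance
drop, one rating-based exclusion retained by override, three merges, 20
final variables), not the original panel's responses.
"""

from __future__ import annotations

import csv
import io
from collections import Counter
from importlib import resources
from pathlib import Path
from typing import Iterable, Literal, Mapping, Optional, Sequence, Union

import pandas as pd
import yaml
from pydantic import BaseModel, Field

from .model import (
    GmfClass,
    LogicStatement,
    PhenotypeModel,
    ValuePredicate,
    ValueSet,
    Variable,
)

__all__ = [
    "PanelResponseGrid",
    "AggregatedValueSet",
    "InclusionDecision",
    "ConformanceResult",
    "PanelRegistry",
    "aggregate_values_ex1",
    "decide_inclusion_ex2",
    "check_conformance",
    "build_model_from_panel",
    "build_exercise_grid",
    "read_panel_grids",
    "read_registry",
    "load_packaged_fixture",
]

DECLINED = "declined"


class PanelResponseGrid(BaseModel):
    """One panelist's EX1 value assignments and EX2 ratings."""

    panelist_id: str
    #: variable -> gmf class (1..3) -> set of assigned value tokens
    ex1: dict[str, dict[int, set[str]]] = Field(default_factory=dict)
    #: variable -> rating 1..5, or None when the panelist declined
    ex2: dict[str, Optional[int]] = Field(default_factory=dict)
    suggestions: list[str] = Field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return sum(len(by_class) for by_class in self.ex1.values())


class AggregatedValueSet(BaseModel):
    variable: str
    per_class_values: dict[int, set[str]] = Field(default_factory=dict)
    aggregation_path: dict[int, Literal["consensus", "tie_or_multiple", "union_fallback"]] = Field(
        default_factory=dict
    )
    unresolved_classes: set[int] = Field(default_factory=set)


class InclusionDecision(BaseModel):
    variable: str
    decision: Literal["include", "include_split", "exclude"]
    rating_summary: list[Union[int, str]] = Field(default_factory=list)
    basis: str = ""


class ConformanceResult(BaseModel):
    variable: str
    values_deviate_across_classes: bool
    rated_ge3: bool
    conformant: bool
    final_status: Literal["retained", "dropped", "retained_by_override"]


class PanelRegistry(BaseModel):
    """The Phase-2 registry the exercise runs over: candidate variables with
    their structure and value sets."""

    variables: list[Variable]
    value_sets: list[ValueSet]
    domains: list[str]

    @property
    def n_unique(self) -> int:
        return sum(1 for v in self.variables if v.kind == "unique")

    @property
    def n_derived(self) -> int:
        return sum(1 for v in self.variables if v.kind == "derived")

    def value_set_by_name(self, name: str) -> ValueSet:
        for vs in self.value_sets:
            if vs.name == name:
                return vs
        raise KeyError(name)


def aggregate_values_ex1(
    variable: str, responses: Mapping[int, Sequence[set[str]]]
) -> AggregatedValueSet:
    """Aggregate all panelists' EX1 assignments for one variable.

    ``responses`` maps GMF class (1..3) to the per-panelist assigned sets.
    Empty cells across all panelists are flagged unresolved, never defaulted.
    The result is permutation-invariant over panelists.
    """
    agg = AggregatedValueSet(variable=variable)
    for gmf_class, sets in responses.items():
        non_empty = [s for s in sets if s]
        if not non_empty:
            agg.unresolved_classes.add(gmf_class)
            continue
        votes = Counter()
        for s in non_empty:
            for tok in s:
                votes[tok] += 1
        top = max(votes.values())
        modal = {tok for tok, n in votes.items() if n == top}
        if len(modal) == 1 and top > len(non_empty) / 2:
            agg.per_class_values[gmf_class] = modal
            agg.aggregation_path[gmf_class] = "consensus"
        elif len(modal) == 2:
            agg.per_class_values[gmf_class] = modal
            agg.aggregation_path[gmf_class] = "tie_or_multiple"
        else:
            agg.per_class_values[gmf_class] = set().union(*non_empty)
            agg.aggregation_path[gmf_class] = "union_fallback"
    return agg


def decide_inclusion_ex2(
    variable: str, ratings: Sequence[Union[int, str, None]]
) -> InclusionDecision:
    """Decide inclusion of a variable from its EX2 ratings.

    Declined ratings leave the denominator.  Include on a strict majority of
    non-declined ratings >= 3; an exact even split across the 2/3 boundary is
    an inclusion of its own kind; a strict majority <= 2 excludes.
    """
    summary: list[Union[int, str]] = [
        DECLINED if r in (None, DECLINED) else int(r) for r in ratings
    ]
    numeric = [r for r in summary if r != DECLINED]
    if any(not (1 <= r <= 5) for r in numeric):
        raise ValueError(f"rating out of range for {variable!r}: {numeric}")
    if not numeric:
        return InclusionDecision(
            variable=variable, decision="exclude", rating_summary=summary, basis="no_ratings"
        )
    n_hi = sum(1 for r in numeric if r >= 3)
    n_lo = len(numeric) - n_hi
    if n_hi > len(numeric) / 2:
        decision, basis = "include", "consensus_ge3"
    elif n_hi == n_lo:
        decision, basis = "include_split", "split_across_boundary"
    else:
        decision, basis = "exclude", "consensus_le2"
    return InclusionDecision(
        variable=variable, decision=decision, rating_summary=summary, basis=basis
    )


def check_conformance(
    aggregated: AggregatedValueSet,
    inclusion: InclusionDecision,
    overrides: Iterable[str] = (),
) -> ConformanceResult:
    """Quality-control check of EX1 value deviation against EX2 inclusion.

    A variable conforms when its aggregated per-class value sets are not all
    pairwise equal and the rating decision included it; otherwise it is
    dropped unless named in ``overrides`` (domain-expert discretion, recorded
    as retained_by_override).
    """
    if aggregated.variable != inclusion.variable:
        raise ValueError("aggregated and inclusion refer to different variables")
    sets = [aggregated.per_class_values.get(c, set()) for c in (1, 2, 3)]
    deviates = not (sets[0] == sets[1] == sets[2])
    rated = inclusion.decision in ("include", "include_split")
    conformant = deviates and rated
    if conformant:
        status = "retained"
    elif aggregated.variable in set(overrides):
        status = "retained_by_override"
    else:
        status = "dropped"
    return ConformanceResult(
        variable=aggregated.variable,
        values_deviate_across_classes=deviates,
        rated_ge3=rated,
        conformant=conformant,
        final_status=status,
    )


def build_exercise_grid(registry: PanelRegistry) -> pd.DataFrame:
    """Blank EX1 exercise for one panelist: one row per variable x class."""
    rows = [
        {"variable": v.name, "gmf_class": c, "assigned_values": ""}
        for v in registry.variables
        for c in (1, 2, 3)
    ]
    return pd.DataFrame(rows, columns=["variable", "gmf_class", "assigned_values"])


class PanelBuildResult(BaseModel):
    model: PhenotypeModel
    audit: list[dict] = Field(default_factory=list)

    def audit_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.audit,
            columns=[
                "variable",
                "decision",
                "basis",
                "values_deviate_across_classes",
                "conformant",
                "aggregation_paths",
                "status",
            ],
        )


def build_model_from_panel(
    grids: Sequence[PanelResponseGrid],
    registry: PanelRegistry,
    merges: Mapping[str, str] | None = None,
    overrides: Iterable[str] = (),
    age_band: tuple[int, int] = (6, 18),
) -> PanelBuildResult:
    """Run the full pipeline: EX1 aggregation -> EX2 inclusion ->
    conformance -> merges -> phenotype model with membership predicates.

    Every registry variable appears in the audit as exactly one of
    retained / retained_by_override / dropped / merged.
    """
    merges = dict(merges or {})
    if not grids:
        raise ValueError("no panel grids supplied")
    registry_names = [v.name for v in registry.variables]
    for g in grids:
        if set(g.ex1) != set(registry_names):
            missing = set(registry_names) ^ set(g.ex1)
            raise ValueError(
                f"grid {g.panelist_id!r} does not cover the registry (diff: {sorted(missing)})"
            )
    for src, tgt in merges.items():
        if src not in registry_names or tgt not in registry_names:
            raise ValueError(f"merge directive {src!r} -> {tgt!r} names unknown variable")

    audit: list[dict] = []
    survivors: dict[str, AggregatedValueSet] = {}
    for var in registry.variables:
        responses = {
            c: [g.ex1[var.name].get(c, set()) for g in grids] for c in (1, 2, 3)
        }
        agg = aggregate_values_ex1(var.name, responses)
        inc = decide_inclusion_ex2(var.name, [g.ex2.get(var.name) for g in grids])
        conf = check_conformance(agg, inc, overrides)
        status = conf.final_status
        if status != "dropped" and var.name in merges:
            status = f"merged_into:{merges[var.name]}"
        elif status != "dropped":
            survivors[var.name] = agg
        audit.append(
            {
                "variable": var.name,
                "decision": inc.decision,
                "basis": inc.basis,
                "values_deviate_across_classes": conf.values_deviate_across_classes,
                "conformant": conf.conformant,
                "aggregation_paths": ";".join(
                    f"{c}:{agg.aggregation_path[c]}" for c in sorted(agg.aggregation_path)
                ),
                "status": status,
            }
        )

    variables = [v.model_copy(deep=True) for v in registry.variables if v.name in survivors]
    used_vs = {v.value_set for v in variables}
    statements: list[LogicStatement] = []
    for var in variables:
        agg = survivors[var.name]
        for c in (1, 2, 3):
            toks = agg.per_class_values.get(c)
            if not toks:
                var.rule_incomplete = True
                continue
            statements.append(
                LogicStatement(
                    variable=var.name,
                    gmf_class=GmfClass(c),
                    rule=f"Panel-aggregated values: {', '.join(sorted(toks))}",
                    predicate=ValuePredicate(kind="membership", tokens=sorted(toks)),
                    provenance="paper",
                )
            )
    model = PhenotypeModel(
        name="gmfpm-panel-built",
        age_band=age_band,
        domains=list(registry.domains),
        value_sets=[vs for vs in registry.value_sets if vs.name in used_vs],
        variables=variables,
        statements=statements,
        metadata={"source": "expert-panel aggregation", "n_panelists": len(grids)},
    )
    return PanelBuildResult(model=model, audit=audit)


# ---------------------------------------------------------------------------
# Delimited I/O and the packaged synthetic fixture
# ---------------------------------------------------------------------------

def _read_text(source) -> str:
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        return Path(source).read_text()
    if hasattr(source, "read"):
        return source.read()
    return str(source)


def read_panel_grids(ex1_source, ex2_source) -> list[PanelResponseGrid]:
    """Read EX1 assignments (panelist_id, variable, gmf_class,
    assigned_values '|'-joined) and EX2 ratings (panelist_id, variable,
    rating or 'declined') into one grid per panelist."""
    grids: dict[str, PanelResponseGrid] = {}
    for row in csv.DictReader(io.StringIO(_read_text(ex1_source))):
        g = grids.setdefault(
            row["panelist_id"], PanelResponseGrid(panelist_id=row["panelist_id"])
        )
        toks = {t.strip() for t in row["assigned_values"].split("|") if t.strip()}
        g.ex1.setdefault(row["variable"], {})[int(row["gmf_class"])] = toks
    for row in csv.DictReader(io.StringIO(_read_text(ex2_source))):
        g = grids.setdefault(
            row["panelist_id"], PanelResponseGrid(panelist_id=row["panelist_id"])
        )
        r = row["rating"].strip().lower()
        g.ex2[row["variable"]] = None if r == DECLINED else int(r)
    return [grids[k] for k in sorted(grids)]


def read_registry(registry_source, value_sets_source) -> PanelRegistry:
    """Read the candidate-variable registry (CSV with '|'-joined element
    names) and its value-set definitions (YAML)."""
    doc = yaml.safe_load(_read_text(value_sets_source))
    value_sets = [ValueSet.model_validate(d) for d in doc["value_sets"]]
    domains = list(doc.get("domains", []))
    variables = []
    for row in csv.DictReader(io.StringIO(_read_text(registry_source))):
        elements = [{"name": e.strip()} for e in row["elements"].split("|") if e.strip()]
        variables.append(
            Variable(
                name=row["variable"],
                kind=row["kind"],
                domain=row["domain"],
                value_set=row["value_set"],
                elements=elements,
            )
        )
    return PanelRegistry(variables=variables, value_sets=value_sets, domains=domains)


def _fixture_path(name: str) -> Path:
    return Path(str(resources.files("gmfpm").joinpath(f"data/panel/{name}")))


def load_packaged_fixture():
    """Load the packaged synthetic panel fixture.

    Returns ``(grids, registry, merges, overrides)`` reconstructing the
    published exercise shape: a 31-variable registry (14 unique, 17
    derived), four panelists, three merge directives and one override.
    """
    grids = read_panel_grids(_fixture_path("ex1_assignments.csv"), _fixture_path("ex2_ratings.csv"))
    registry = read_registry(
        _fixture_path("registry.csv"), _fixture_path("registry_value_sets.yaml")
    )
    config = yaml.safe_load(_fixture_path("panel_config.yaml").read_text())
    return grids, registry, dict(config.get("merges", {})), list(config.get("overrides", []))
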