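"""Declarative phenotype model for gross motor function (GMF).

The model is rules-as-data: domains, variables, data element concepts, value
sets and class-stratified logic statements are all carried by one structured
YAML document (schema in ``data/model_definition.schema.json``).  The packaged
definition covers patients aged 6-18 and organises 20 variables / 65 data
element concepts into five performance-related domains; each variable carries
one logic statement per GMF class stating which values instantiate membership
in that class.

GMF classes collapse the five-level Gross Motor Function Classification
System (GMFCS): levels I-II (ambulatory without assistive devices) form
Class 1, level III (assistive-device users) forms Class 2, and levels IV-V
(significant ambulatory limitation) form Class 3.
"""

from __future__ import annotations

import enum
from importlib import resources
from pathlib import Path
from typing import Literal, Mapping, Optional, Union

import yaml
from pydantic import BaseModel, Field, ValidationError, field_validator, model_validator

__all__ = [
    "GmfcsLevel",
    "GmfClass",
    "ValueSet",
    "DataElement",
    "Variable",
    "ValuePredicate",
    "LogicStatement",
    "PhenotypeModel",
    "ValidationIssue",
    "ValidationReport",
    "ModelDefinitionError",
    "ModelValidationError",
    "UnknownTokenError",
    "collapse_gmfcs",
    "canonicalize_token",
    "load_model",
    "serialize_model",
    "save_model",
    "load_packaged_model",
    "packaged_model_path",
]


class GmfcsLevel(enum.IntEnum):
    """Five-level ordinal GMFCS (I least limited ... V most limited)."""

    I = 1
    II = 2
    III = 3
    IV = 4
    V = 5

    @classmethod
    def parse(cls, token: Union[str, int, "GmfcsLevel"]) -> "GmfcsLevel":
        if isinstance(token, GmfcsLevel):
            return token
        if isinstance(token, int):
            return cls(token)
        t = str(token).strip().upper()
        if t in cls.__members__:
            return cls[t]
        return cls(int(t))


class GmfClass(enum.IntEnum):
    """Three-level ordinal GMF phenotype class (1 least, 3 most limited)."""

    C1 = 1
    C2 = 2
    C3 = 3

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return str(self.value)


#: GMFCS level -> GMF phenotype class.
_COLLAPSE: Mapping[GmfcsLevel, GmfClass] = {
    GmfcsLevel.I: GmfClass.C1,
    GmfcsLevel.II: GmfClass.C1,
    GmfcsLevel.III: GmfClass.C2,
    GmfcsLevel.IV: GmfClass.C3,
    GmfcsLevel.V: GmfClass.C3,
}


def collapse_gmfcs(level: Union[GmfcsLevel, str, int]) -> GmfClass:
    """Collapse a GMFCS level into its GMF phenotype class.

    I, II -> Class 1; III -> Class 2; IV, V -> Class 3.  Total on the enum.
    """
    return _COLLAPSE[GmfcsLevel.parse(level)]


class UnknownTokenError(ValueError):
    """A raw value token matched neither a canonical token nor an alias."""

    def __init__(self, token: str, value_set: str):
        self.token = token
        self.value_set = value_set
        super().__init__(f"unknown token {token!r} for value set {value_set!r}")


class ModelDefinitionError(ValueError):
    """The definition document does not conform to the model schema."""


class ValueSet(BaseModel):
    """An enumerated admissible value list for a data element or variable.

    ``values`` are ordered; for ``kind='ordinal'`` the order is the severity
    order used by rule evaluation (e.g. the Modified Ashworth Scale
    0 < 1 < 1.5 < 2 < 3 < 4, where "1+" is an alias of "1.5").
    """

    name: str
    kind: Literal["binary", "ordinal", "nominal"]
    values: list[str]
    aliases: dict[str, str] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self) -> "ValueSet":
        if not self.values:
            raise ValueError(f"value set {self.name!r} has no values")
        lowered = [v.strip().lower() for v in self.values]
        if len(set(lowered)) != len(lowered):
            raise ValueError(f"value set {self.name!r} has duplicate tokens")
        if self.kind == "binary" and set(self.values) != {"Yes", "No"}:
            raise ValueError(
                f"binary value set {self.name!r} must have exactly tokens Yes/No"
            )
        for alias, target in self.aliases.items():
            if target not in self.values:
                raise ValueError(
                    f"alias {alias!r} of value set {self.name!r} points at "
                    f"unknown token {target!r}"
                )
        return self

    def canonicalize(self, raw: str) -> str:
        """Resolve a raw token to its canonical form.

        Matching is whitespace-trimmed and case-insensitive, first against the
        canonical tokens, then against the alias map.  Raises
        :class:`UnknownTokenError` if nothing matches.
        """
        t = str(raw).strip()
        if not t:
            raise UnknownTokenError(raw, self.name)
        low = t.lower()
        for v in self.values:
            if v.lower() == low:
                return v
        for alias, target in self.aliases.items():
            if alias.lower() == low:
                return target
        raise UnknownTokenError(raw, self.name)

    def rank(self, token: str) -> int:
        """Position of a canonical token in the (severity) order."""
        return self.values.index(token)


def canonicalize_token(raw: str, value_set: ValueSet) -> str:
    """Module-level alias for :meth:`ValueSet.canonicalize`."""
    return value_set.canonicalize(raw)


class DataElement(BaseModel):
    """One discrete, coded EHR field (an OMOP custom concept).

    ``concept_code`` is the printed OMOP custom concept identifier when the
    source material prints one (e.g. 2500010257 for Respiratory support) and
    None otherwise, in which case records are matched by element name.
    """

    name: str
    concept_code: Optional[int] = None


class ValuePredicate(BaseModel):
    """Machine predicate of one logic statement.

    Exactly one of three kinds:

    ``membership``
        For unique variables and derived ordinal variables: the resolved
        variable value must be one of ``tokens``.  For derived binary
        variables ``tokens`` are element names and the predicate matches when
        any positively-observed ("Yes") element is in the set.
    ``count_threshold``
        Over a derived variable's binary elements: compare the number of
        elements carrying ``positive_token`` against ``k`` with
        ``comparator`` (eq / ge / le).
    ``all_of``
        Every element of the derived variable carries ``token``.
    """

    kind: Literal["membership", "count_threshold", "all_of"]
    tokens: Optional[list[str]] = None
    comparator: Optional[Literal["eq", "ge", "le"]] = None
    k: Optional[int] = None
    positive_token: Optional[str] = None
    token: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "ValuePredicate":
        if self.kind == "membership":
            if not self.tokens:
                raise ValueError("membership predicate requires non-empty tokens")
            if any(
                x is not None for x in (self.comparator, self.k, self.positive_token, self.token)
            ):
                raise ValueError("membership predicate carries only tokens")
        elif self.kind == "count_threshold":
            if self.comparator is None or self.k is None or self.positive_token is None:
                raise ValueError(
                    "count_threshold predicate requires comparator, k and positive_token"
                )
            if self.k < 0:
                raise ValueError("count_threshold k must be >= 0")
            if self.tokens is not None or self.token is not None:
                raise ValueError("count_threshold predicate carries only its own fields")
        else:  # all_of
            if self.token is None:
                raise ValueError("all_of predicate requires token")
            if any(
                x is not None for x in (self.tokens, self.comparator, self.k, self.positive_token)
            ):
                raise ValueError("all_of predicate carries only token")
        return self


class LogicStatement(BaseModel):
    """One class-stratified rule: human-readable stem/rule/qualifier plus a
    machine predicate, for one variable and one GMF class.

    ``provenance`` records whether the predicate transcribes published rule
    content (``paper``) or is a clinically monotone default supplied by this
    package (``default``) and overridable via the definition document.
    """

    variable: str
    gmf_class: GmfClass
    stem: str = ""
    rule: str = ""
    qualifier: str = ""
    predicate: ValuePredicate
    provenance: Literal["paper", "default"] = "default"

    @field_validator("gmf_class", mode="before")
    @classmethod
    def _coerce_class(cls, v):
        return GmfClass(int(v)) if not isinstance(v, GmfClass) else v


class Variable(BaseModel):
    """A model variable: one data element concept (``unique``) or several
    concepts sharing one value-set structure (``derived``)."""

    name: str
    kind: Literal["unique", "derived"]
    domain: str
    value_set: str
    elements: list[DataElement]
    rule_incomplete: bool = False

    @model_validator(mode="after")
    def _check(self) -> "Variable":
        if self.kind == "unique" and len(self.elements) != 1:
            raise ValueError(f"unique variable {self.name!r} must have exactly one element")
        if self.kind == "derived" and len(self.elements) < 2:
            raise ValueError(f"derived variable {self.name!r} must have >= 2 elements")
        names = [e.name.strip().lower() for e in self.elements]
        if len(set(names)) != len(names):
            raise ValueError(f"variable {self.name!r} repeats an element name")
        return self


#: Canonical domain names of the packaged model.
CANONICAL_DOMAINS = (
    "Neurologic Function",
    "Mobility Performance",
    "Activity Performance",
    "Motor Performance",
    "Device Use",
)

#: Header spellings accepted for domains ("Devices Used" is the table-header
#: alias of the canonical "Device Use").
DOMAIN_ALIASES = {"Devices Used": "Device Use"}


class ValidationIssue(BaseModel):
    severity: Literal["error", "warning"]
    path: str
    message: str

    def __str__(self) -> str:
        return f"[{self.severity}] {self.path}: {self.message}"


class ValidationReport(BaseModel):
    issues: list[ValidationIssue] = Field(default_factory=list)

    @property
    def errors(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "error"]

    @property
    def warnings(self) -> list[ValidationIssue]:
        return [i for i in self.issues if i.severity == "warning"]

    @property
    def ok(self) -> bool:
        return not self.errors

    def add(self, severity: str, path: str, message: str) -> None:
        self.issues.append(ValidationIssue(severity=severity, path=path, message=message))

    def __str__(self) -> str:
        if not self.issues:
            return "validation: clean"
        return "\n".join(str(i) for i in self.issues)


class ModelValidationError(ValueError):
    """The definition parsed but violates model invariants."""

    def __init__(self, report: ValidationReport):
        self.report = report
        super().__init__(str(report))


class PhenotypeModel(BaseModel):
    """The full declarative phenotype model.

    Cross-references (variable -> value set, statement -> variable) are by
    name so the model round-trips losslessly through its YAML form.
    """

    schema_version: int = 1
    name: str = "gmfpm"
    age_band: tuple[int, int] = (6, 18)
    domains: list[str] = Field(default_factory=list)
    value_sets: list[ValueSet] = Field(default_factory=list)
    variables: list[Variable] = Field(default_factory=list)
    statements: list[LogicStatement] = Field(default_factory=list)
    metadata: dict = Field(default_factory=dict)

    # -- lookups -----------------------------------------------------------
    def value_set_by_name(self, name: str) -> ValueSet:
        for vs in self.value_sets:
            if vs.name == name:
                return vs
        raise KeyError(f"no value set named {name!r}")

    def variable_by_name(self, name: str) -> Variable:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(f"no variable named {name!r}")

    def statements_for(self, variable: str, gmf_class: Optional[GmfClass] = None) -> list[LogicStatement]:
        out = [s for s in self.statements if s.variable == variable]
        if gmf_class is not None:
            out = [s for s in out if s.gmf_class == gmf_class]
        return out

    def variables_in_domain(self, domain: str) -> list[Variable]:
        canonical = DOMAIN_ALIASES.get(domain, domain)
        return [v for v in self.variables if DOMAIN_ALIASES.get(v.domain, v.domain) == canonical]

    def element_index(self) -> dict[Union[int, str], tuple[Variable, DataElement]]:
        """Map concept_code (int) and lower-cased element name (str) to
        (variable, element)."""
        idx: dict[Union[int, str], tuple[Variable, DataElement]] = {}
        for var in self.variables:
            for el in var.elements:
                if el.concept_code is not None:
                    idx[el.concept_code] = (var, el)
                idx[el.name.strip().lower()] = (var, el)
        return idx

    # -- counts ------------------------------------------------------------
    @property
    def n_variables(self) -> int:
        return len(self.variables)

    @property
    def n_elements(self) -> int:
        return sum(len(v.elements) for v in self.variables)

    @property
    def n_domains(self) -> int:
        return len(self.domains)

    # -- validation --------------------------------------------------------
    def validate_invariants(self) -> ValidationReport:
        """Cross-reference and invariant checks; returns a report, raising
        nothing.  Structural (per-type) invariants were already enforced by
        the schema."""
        rep = ValidationReport()
        if not self.variables:
            rep.add("warning", "variables", "model defines zero variables")

        seen_domains = set()
        for d in self.domains:
            canon = DOMAIN_ALIASES.get(d, d)
            if canon in seen_domains:
                rep.add("error", f"domains.{d}", "duplicate domain")
            seen_domains.add(canon)

        vs_names = {vs.name for vs in self.value_sets}
        var_names = set()
        code_paths: dict[int, list[str]] = {}
        for vi, var in enumerate(self.variables):
            path = f"variables[{vi}].{var.name}"
            if var.name in var_names:
                rep.add("error", path, "duplicate variable name")
            var_names.add(var.name)
            canon = DOMAIN_ALIASES.get(var.domain, var.domain)
            if canon not in seen_domains:
                rep.add("error", path, f"unknown domain {var.domain!r}")
            if var.value_set not in vs_names:
                rep.add("error", path, f"unknown value set {var.value_set!r}")
            for el in var.elements:
                if el.concept_code is not None:
                    code_paths.setdefault(el.concept_code, []).append(f"{path}.{el.name}")
        for code, paths in code_paths.items():
            if len(paths) > 1:
                rep.add(
                    "error",
                    "; ".join(paths),
                    f"concept_code {code} repeated across elements",
                )

        by_var: dict[str, set[GmfClass]] = {}
        for si, st in enumerate(self.statements):
            path = f"statements[{si}].{st.variable}.class{int(st.gmf_class)}"
            if st.variable not in var_names:
                rep.add("error", path, "statement references unknown variable")
                continue
            var = self.variable_by_name(st.variable)
            by_var.setdefault(st.variable, set()).add(st.gmf_class)
            issues = _check_predicate(st.predicate, var, self)
            for msg in issues:
                rep.add("error", path, msg)

        for var in self.variables:
            classes = by_var.get(var.name, set())
            if not var.rule_incomplete and classes != set(GmfClass):
                missing = sorted(int(c) for c in set(GmfClass) - classes)
                rep.add(
                    "error",
                    f"variables.{var.name}",
                    f"missing statements for classes {missing} and not marked rule-incomplete",
                )
        return rep


def _check_predicate(pred: ValuePredicate, var: Variable, model: PhenotypeModel) -> list[str]:
    """Consistency of a predicate with its variable's structure."""
    out: list[str] = []
    try:
        vs = model.value_set_by_name(var.value_set)
    except KeyError:
        return [f"variable {var.name!r} has unknown value set"]
    if pred.kind == "membership":
        element_names = {e.name for e in var.elements}
        allowed = set(vs.values) | (element_names if var.kind == "derived" else set())
        bad = set(pred.tokens or []) - allowed
        if bad:
            out.append(
                f"membership tokens {sorted(bad)} outside value set {vs.name!r}"
                + (" and element names" if var.kind == "derived" else "")
            )
    elif pred.kind == "count_threshold":
        if vs.kind != "binary":
            out.append("count_threshold requires a binary element value set")
        elif pred.positive_token not in vs.values:
            out.append(f"positive_token {pred.positive_token!r} outside value set")
        if pred.k is not None and pred.k > len(var.elements):
            out.append(f"k={pred.k} exceeds element count {len(var.elements)}")
    else:  # all_of
        if pred.token not in vs.values:
            out.append(f"all_of token {pred.token!r} outside value set")
    return out


# ---------------------------------------------------------------------------
# Loading / serialization
# ---------------------------------------------------------------------------

def _synthesize_text(st: LogicStatement, model: PhenotypeModel) -> None:
    """Fill any empty stem/rule/qualifier with generated human-readable text
    so every statement carries the full triple."""
    if not st.stem:
        st.stem = f"A patient in GMF Class {int(st.gmf_class)}"
    p = st.predicate
    if not st.rule:
        if p.kind == "membership":
            st.rule = f"has {st.variable} in {{{', '.join(p.tokens or [])}}}"
        elif p.kind == "count_threshold":
            cmp_word = {"eq": "exactly", "ge": "at least", "le": "at most"}[p.comparator or "eq"]
            st.rule = (
                f"has {cmp_word} {p.k} of the {st.variable} elements "
                f"recorded {p.positive_token}"
            )
        else:
            st.rule = f"has every {st.variable} element recorded {p.token}"
    if not st.qualifier:
        var = model.variable_by_name(st.variable)
        st.qualifier = (
            f"over the value set of {var.value_set!r} within the model age band "
            f"{model.age_band[0]}-{model.age_band[1]} years"
        )


def load_model(source: Union[str, Path, Mapping], strict: bool = True) -> PhenotypeModel:
    """Load a phenotype model from a YAML document (path, text, or mapping).

    Structural schema violations raise :class:`ModelDefinitionError` carrying
    the offending path.  Cross-reference invariants are collected into a
    validation report; with ``strict=True`` (default) any error raises
    :class:`ModelValidationError` whose ``report`` lists every violation.
    The report is attached to the returned model as ``model.metadata
    ['validation']`` summary either way; warnings never raise.
    """
    if isinstance(source, Mapping):
        doc = dict(source)
    else:
        s = str(source)
        is_path = isinstance(source, Path) or ("\n" not in s and Path(s).exists())
        text = Path(s).read_text() if is_path else s
        doc = yaml.safe_load(text)
        if doc is None:
            doc = {}
    if not isinstance(doc, Mapping):
        raise ModelDefinitionError("definition document must be a mapping")
    try:
        model = PhenotypeModel.model_validate(doc)
    except ValidationError as e:
        locs = "; ".join(
            "/".join(str(p) for p in err["loc"]) + ": " + err["msg"] for err in e.errors()
        )
        raise ModelDefinitionError(f"schema violation: {locs}") from e
    report = model.validate_invariants()
    if strict and not report.ok:
        raise ModelValidationError(report)
    for st in model.statements:
        _synthesize_text(st, model)
    model.metadata.setdefault("validation", {})
    model.metadata["validation"] = {
        "errors": len(report.errors),
        "warnings": len(report.warnings),
    }
    return model


def serialize_model(model: PhenotypeModel) -> dict:
    """Plain-dict form of the model; ``load_model(serialize_model(m))``
    compares equal to ``m`` field-by-field."""
    d = model.model_dump(mode="json")
    d.pop("metadata", None)
    d["metadata"] = {k: v for k, v in model.metadata.items() if k != "validation"}
    return d


def save_model(model: PhenotypeModel, path: Union[str, Path]) -> None:
    Path(path).write_text(yaml.safe_dump(serialize_model(model), sort_keys=False))


def packaged_model_path() -> Path:
    """Filesystem path of the packaged GMF phenotype model definition."""
    return Path(str(resources.files("gmfpm").joinpath("data/gmfpm_model.yaml")))


def load_packaged_model() -> PhenotypeModel:
    """Load the packaged 20-variable / 65-element / 5-domain GMF model."""
    return load_model(packaged_model_path())
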