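"""OMOP-flavored table ingestion and per-patient feature resolution.

Reads delimited person / observation tables (the columns of an OMOP
observation table that the phenotype model needs: person, concept, value,
date) and resolves raw observation records into one feature vector per
patient over the model's variables, inside an age band and a look-back
window anchored at an index date.

Resolution rules: per data element the most recent observation inside the
window wins; distinct same-day values for one element are a documentation
conflict and make the element unobserved; tokens are canonicalized against
the element's value set; a derived binary variable resolves to its
per-element Yes/No map, a derived ordinal variable (the MAS tone variables)
to the most severe observed element value, and a unique variable to its
single element's token.
"""

from __future__ import annotations

import datetime as dt
import io
import logging
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd
from pydantic import BaseModel, Field

from .model import PhenotypeModel, UnknownTokenError, Variable

__all__ = [
    "Person",
    "ObservationRecord",
    "PatientFeatureVector",
    "TableReadResult",
    "ExtractionResult",
    "SchemaError",
    "read_tables",
    "extract_features",
    "DEFAULT_WINDOW_DAYS",
]

logger = logging.getLogger(__name__)

#: Look-back window; GMFCS is stable on the year scale in the 6-18 band.
DEFAULT_WINDOW_DAYS = 365

PERSON_COLUMNS = ["person_id", "birth_date"]
OBSERVATION_COLUMNS = ["person_id", "concept_code", "concept_name", "value", "observation_date"]


class SchemaError(ValueError):
    """A mandatory column is missing from an input table."""


class Person(BaseModel):
    person_id: str
    birth_date: dt.date


class ObservationRecord(BaseModel):
    person_id: str
    concept_code: Optional[int] = None
    concept_name: str = ""
    value: str
    observation_date: dt.date


class PatientFeatureVector(BaseModel):
    """Per-patient resolved values for every model variable.

    ``values`` maps variable name to a canonical token (unique and derived
    ordinal variables) or an element-name -> token map (derived binary
    variables); every model variable appears in exactly one of ``values`` /
    ``missing_variables``.
    """

    person_id: str
    index_date: dt.date
    age_years: int
    values: dict[str, Union[str, dict[str, str]]] = Field(default_factory=dict)
    missing_variables: set[str] = Field(default_factory=set)


class TableReadResult(BaseModel):
    persons: list[Person]
    observations: list[ObservationRecord]
    rejects: list[dict] = Field(default_factory=list)

    def rejects_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rejects, columns=["table", "row", "reason"])


class ExtractionResult(BaseModel):
    features: list[PatientFeatureVector]
    n_age_excluded: int = 0
    n_no_observations: int = 0
    conflicts: list[dict] = Field(default_factory=list)
    token_rejects: list[dict] = Field(default_factory=list)
    n_unknown_concepts: int = 0


def _read_delimited(source, columns: Sequence[str], table: str) -> pd.DataFrame:
    """Read comma- (default) or tab-delimited text with a mandatory header."""
    if isinstance(source, (str, Path)) and "\n" not in str(source):
        text = Path(source).read_text()
    elif hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
    sep = "\t" if "\t" in text.splitlines()[0] else "," if text.strip() else ","
    df = pd.read_csv(io.StringIO(text), sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table is missing mandatory column(s) {missing}")
    return df


def _parse_date(token: str) -> dt.date:
    return dt.date.fromisoformat(str(token).strip())


def read_tables(person_source, observation_source) -> TableReadResult:
    """Parse person and observation tables.

    Sources may be paths, file objects, or raw delimited text.  Malformed
    rows (bad dates, empty values) go to the rejects report with their row
    number; a missing mandatory column is fatal (:class:`SchemaError`).
    """
    persons: list[Person] = []
    observations: list[ObservationRecord] = []
    rejects: list[dict] = []

    pdf = _read_delimited(person_source, PERSON_COLUMNS, "person")
    for i, row in pdf.iterrows():
        try:
            persons.append(
                Person(person_id=str(row["person_id"]).strip(), birth_date=_parse_date(row["birth_date"]))
            )
        except ValueError as e:
            rejects.append({"table": "person", "row": int(i) + 2, "reason": str(e)})

    odf = _read_delimited(observation_source, OBSERVATION_COLUMNS, "observation")
    if odf.empty:
        logger.warning("observation table has a valid header but zero rows")
    for i, row in odf.iterrows():
        rownum = int(i) + 2  # 1-based with header
        try:
            raw_code = str(row["concept_code"]).strip()
            code = int(raw_code) if raw_code else None
            value = str(row["value"]).strip()
            if not value:
                raise ValueError("empty value")
            observations.append(
                ObservationRecord(
                    person_id=str(row["person_id"]).strip(),
                    concept_code=code,
                    concept_name=str(row["concept_name"]).strip(),
                    value=value,
                    observation_date=_parse_date(row["observation_date"]),
                )
            )
        except ValueError as e:
            rejects.append({"table": "observation", "row": rownum, "reason": str(e)})

    logger.info(
        "read %d persons, %d observations, %d rejects",
        len(persons), len(observations), len(rejects),
    )
    return TableReadResult(persons=persons, observations=observations, rejects=rejects)


def _age_completed_years(birth: dt.date, at: dt.date) -> int:
    return at.year - birth.year - ((at.month, at.day) < (birth.month, birth.day))


def _resolve_variable(
    var: Variable,
    element_values: dict[str, str],
    model: PhenotypeModel,
) -> Union[str, dict[str, str], None]:
    """Collapse observed element tokens into the variable's resolved value."""
    if not element_values:
        return None
    vs = model.value_set_by_name(var.value_set)
    if var.kind == "unique":
        return next(iter(element_values.values()))
    if vs.kind == "binary":
        return dict(element_values)
    # Derived ordinal (MAS tone) / nominal: most severe observed element.
    return max(element_values.values(), key=vs.rank)


def extract_features(
    persons: Sequence[Person],
    observations: Sequence[ObservationRecord],
    model: PhenotypeModel,
    index_date: Union[dt.date, str],
    window_days: int = DEFAULT_WINDOW_DAYS,
) -> ExtractionResult:
    """Resolve observations into feature vectors for in-age-band persons.

    Persons outside the model age band at ``index_date`` are excluded and
    counted; persons with no usable in-window observation are emitted with
    every variable missing (and counted).  Observations whose concept is not
    in the model are ignored (a CDM carries thousands of irrelevant
    concepts).
    """
    if window_days <= 0:
        raise ValueError("window_days must be positive")
    if isinstance(index_date, str):
        index_date = dt.date.fromisoformat(index_date)
    window_start = index_date - dt.timedelta(days=window_days)

    idx = model.element_index()
    lo, hi = model.age_band

    # person -> variable -> element -> (date, canonical token) best-so-far,
    # with same-day distinct values collapsing to a conflict marker.
    per_person: dict[str, dict[str, dict[str, tuple]] ] = {}
    conflicts: list[dict] = []
    token_rejects: list[dict] = []
    n_unknown = 0

    for rec in observations:
        key = rec.concept_code if rec.concept_code is not None else rec.concept_name.strip().lower()
        hit = idx.get(key)
        if hit is None and rec.concept_code is not None:
            hit = idx.get(rec.concept_name.strip().lower())
        if hit is None:
            n_unknown += 1
            logger.debug("ignoring observation with unknown concept %r", key)
            continue
        var, el = hit
        if not (window_start <= rec.observation_date <= index_date):
            continue
        vs = model.value_set_by_name(var.value_set)
        try:
            token = vs.canonicalize(rec.value)
        except UnknownTokenError as e:
            token_rejects.append(
                {"person_id": rec.person_id, "element": el.name, "value": rec.value, "reason": str(e)}
            )
            continue
        slot = per_person.setdefault(rec.person_id, {}).setdefault(var.name, {})
        prev = slot.get(el.name)
        if prev is None or rec.observation_date > prev[0]:
            slot[el.name] = (rec.observation_date, token)
        elif rec.observation_date == prev[0] and prev[1] is not None and token != prev[1]:
            slot[el.name] = (rec.observation_date, None)  # same-day conflict
            conflicts.append(
                {
                    "person_id": rec.person_id,
                    "element": el.name,
                    "date": rec.observation_date.isoformat(),
                    "values": f"{prev[1]}|{token}",
                }
            )

    features: list[PatientFeatureVector] = []
    n_age_excluded = 0
    n_no_obs = 0
    for person in persons:
        age = _age_completed_years(person.birth_date, index_date)
        if not (lo <= age <= hi):
            n_age_excluded += 1
            continue
        values: dict[str, Union[str, dict[str, str]]] = {}
        missing: set[str] = set()
        obs_vars = per_person.get(person.person_id, {})
        for var in model.variables:
            element_values = {
                el: tok for el, (_, tok) in obs_vars.get(var.name, {}).items() if tok is not None
            }
            resolved = _resolve_variable(var, element_values, model)
            if resolved is None:
                missing.add(var.name)
            else:
                values[var.name] = resolved
        if len(missing) == len(model.variables):
            n_no_obs += 1
        features.append(
            PatientFeatureVector(
                person_id=person.person_id,
                index_date=index_date,
                age_years=age,
                values=values,
                missing_variables=missing,
            )
        )
    return ExtractionResult(
        features=features,
        n_age_excluded=n_age_excluded,
        n_no_observations=n_no_obs,
        conflicts=conflicts,
        token_rejects=token_rejects,
        n_unknown_concepts=n_unknown,
    )
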