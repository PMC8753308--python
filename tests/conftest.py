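import datetime as dt
import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from gmfpm import PatientFeatureVector, load_packaged_fixture, load_packaged_model


@pytest.fixture(scope="session")
def model():
    return load_packaged_model()


@pytest.fixture(scope="session")
def panel_fixture():
    grids, registry, merges, overrides = load_packaged_fixture()
    return {"grids": grids, "registry": registry, "merges": merges, "overrides": overrides}


def make_feature_vector(model, values, missing=(), person_id="P1", age=10):
    """Hand-build a feature vector; variables absent from both arguments are
    marked missing."""
    all_missing = {v.name for v in model.variables if v.name not in set(values)}
    return PatientFeatureVector(
        person_id=person_id,
        index_date=dt.date(2024, 6, 1),
        age_years=age,
        values=dict(values),
        missing_variables=all_missing | set(missing),
    )


def random_feature_vector(model, rng: np.random.Generator, person_id="R1"):
    """Random resolved values over the model's variables, with random
    missingness and partial observation of derived binary variables."""
    values = {}
    missing = set()
    for var in model.variables:
        if rng.random() < 0.15:
            missing.add(var.name)
            continue
        vs = model.value_set_by_name(var.value_set)
        if var.kind == "unique" or vs.kind != "binary":
            values[var.name] = vs.values[rng.integers(len(vs.values))]
        else:
            observed = {}
            for el in var.elements:
                if rng.random() < 0.8:
                    observed[el.name] = "Yes" if rng.random() < 0.5 else "No"
            if observed:
                values[var.name] = observed
            else:
                missing.add(var.name)
    return PatientFeatureVector(
        person_id=person_id,
        index_date=dt.date(2024, 6, 1),
        age_years=int(rng.integers(6, 19)),
        values=values,
        missing_variables=missing,
    )
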