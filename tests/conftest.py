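"""Shared fixtures: schemas, small registries, and a toy separable task.

Expensive objects (a calibrated generator config, a generated registry) are
session-scoped so the suite builds them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from postrosc.data_model import FeatureSchema, PatientRecord
from postrosc.synthetic_cohort import default_config, default_schema, generate


@pytest.fixture(scope="session")
def schema() -> FeatureSchema:
    return default_schema()


@pytest.fixture(scope="session")
def gen_config():
    return default_config(seed=7)


@pytest.fixture(scope="session")
def registry_small(gen_config):
    """400-patient registry plus sidecar from the default generator."""
    return generate(gen_config, n_patients=400, seed=3)


def make_toy_schema(level_counts=(3, 4, 2)) -> FeatureSchema:
    names = [f"f{i}" for i in range(len(level_counts))]
    features = tuple(
        (n, tuple(f"{n}_l{j}" for j in range(k)))
        for n, k in zip(names, level_counts)
    ) + (("ca", ("0", "1")),)
    return FeatureSchema(
        features=features, decision_inputs=tuple(names), ca_feature="ca"
    )


@pytest.fixture(scope="session")
def toy_schema() -> FeatureSchema:
    return make_toy_schema()


def make_toy_records(
    schema: FeatureSchema, n: int, seed: int, separable_on: str | None = None
) -> list[PatientRecord]:
    """Random records; if ``separable_on`` is a feature name, both targets
    equal the indicator of that feature's first level (a separable task)."""
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        values = {}
        for name in schema.decision_inputs:
            levels = schema.levels(name)
            values[name] = levels[rng.integers(len(levels))]
        if separable_on is not None:
            y = int(values[separable_on] == schema.levels(separable_on)[0])
            ca, outcome = y, y
        else:
            ca = int(rng.random() < 0.3)
            outcome = int(rng.random() < 0.5)
        records.append(
            PatientRecord(
                values=values,
                hospital_id=f"H{rng.integers(3)}",
                ca_performed=ca,
                outcome_class=outcome,
            )
        )
    return records


@pytest.fixture(scope="session")
def toy_separable(toy_schema):
    return make_toy_records(toy_schema, 400, seed=11, separable_on="f1")
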