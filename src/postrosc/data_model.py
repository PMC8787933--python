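"""Domain types, validation and delimited-text I/O for patient registries.

A registry is a flat table of post-ROSC OHCA patients.  Every model input is
categorical; the two binary targets are the coronary-angiography (CA)
decision and the CPC-derived outcome class (0 = CPC 1/2 functional,
1 = CPC 3/4/5).  The decision task uses a fixed set of prehospital/arrest
features; the outcome task uses the same features plus CA — CA is the only
new information between the two tasks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import pandas as pd

SPLIT_NAMES = ("train", "validation", "test", "cohort_analysis")

InputSet = Literal["decision", "survival"]


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered categorical feature definitions with model-role markers.

    Parameters
    ----------
    features
        Ordered ``(name, levels)`` pairs.  Level order is meaningful: it fixes
        one-hot column order and embedding-row order, which transfer learning
        relies on.
    decision_inputs
        Feature names used by the CA decision model.
    ca_feature
        Name of the CA feature; the outcome (survival) model consumes
        ``decision_inputs`` plus this feature, and nothing else.
    hospital_field, outcome_field
        Record fields that are never model inputs.
    """

    features: tuple[tuple[str, tuple[str, ...]], ...]
    decision_inputs: tuple[str, ...]
    ca_feature: str = "coronary_angiography"
    hospital_field: str = "hospital_id"
    outcome_field: str = "outcome_class"

    def __post_init__(self) -> None:
        names = [name for name, _ in self.features]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique")
        for name, levels in self.features:
            if len(set(levels)) < 2:
                raise ValueError(f"feature {name!r} needs >=2 distinct levels")
        known = set(names)
        missing = set(self.decision_inputs) - known
        if missing:
            raise ValueError(f"decision_inputs not in schema: {sorted(missing)}")
        if self.ca_feature in self.decision_inputs:
            raise ValueError("CA feature cannot be a decision-model input")
        if self.ca_feature not in known:
            raise ValueError(f"CA feature {self.ca_feature!r} not in schema")
        for f in (self.hospital_field, self.outcome_field):
            if f in known:
                raise ValueError(f"{f!r} must not be a model feature")

    @property
    def survival_inputs(self) -> tuple[str, ...]:
        """Decision inputs plus the CA feature (appended last)."""
        return self.decision_inputs + (self.ca_feature,)

    def inputs(self, input_set: InputSet) -> tuple[str, ...]:
        if input_set == "decision":
            return self.decision_inputs
        if input_set == "survival":
            return self.survival_inputs
        raise ValueError(f"unknown input set {input_set!r}")

    def levels(self, feature: str) -> tuple[str, ...]:
        for name, levels in self.features:
            if name == feature:
                return levels
        raise KeyError(feature)

    def to_json(self, path: str) -> None:
        payload = {
            "features": [[n, list(ls)] for n, ls in self.features],
            "decision_inputs": list(self.decision_inputs),
            "ca_feature": self.ca_feature,
            "hospital_field": self.hospital_field,
            "outcome_field": self.outcome_field,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "FeatureSchema":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(
            features=tuple((n, tuple(ls)) for n, ls in payload["features"]),
            decision_inputs=tuple(payload["decision_inputs"]),
            ca_feature=payload["ca_feature"],
            hospital_field=payload["hospital_field"],
            outcome_field=payload["outcome_field"],
        )


@dataclass(frozen=True)
class PatientRecord:
    """One admitted OHCA patient: covariate levels, hospital, CA, outcome."""

    values: Mapping[str, str]
    hospital_id: str
    ca_performed: int
    outcome_class: int

    def __post_init__(self) -> None:
        if self.ca_performed not in (0, 1):
            raise ValueError("ca_performed must be 0 or 1")
        if self.outcome_class not in (0, 1):
            raise ValueError("outcome_class must be 0 or 1")


@dataclass(frozen=True)
class ValidationReport:
    errors: tuple[str, ...]
    warnings: tuple[str, ...] = ()

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_registry(
    records: Sequence[PatientRecord],
    schema: FeatureSchema,
    input_set: InputSet = "decision",
) -> ValidationReport:
    """Check every record against the schema; report, never raise.

    ``input_set='survival'`` additionally requires the CA field, mirroring the
    outcome model's larger input set.  (CA lives on ``record.ca_performed``,
    so for survival validation the CA feature is always considered present;
    the check kept here is that its serialized levels cover '0'/'1'.)
    """
    errors: list[str] = []
    warnings: list[str] = []
    required = schema.decision_inputs
    level_sets = {name: set(schema.levels(name)) for name in required}
    for i, rec in enumerate(records):
        for name in required:
            if name not in rec.values:
                errors.append(f"record {i}: missing feature {name!r}")
            elif rec.values[name] not in level_sets[name]:
                errors.append(
                    f"record {i}: unknown level {rec.values[name]!r} "
                    f"for feature {name!r}"
                )
    if input_set == "survival":
        ca_levels = set(schema.levels(schema.ca_feature))
        if not {"0", "1"} <= ca_levels:
            errors.append(
                f"CA feature {schema.ca_feature!r} levels {sorted(ca_levels)} "
                "do not cover binary codes '0'/'1'"
            )
    return ValidationReport(errors=tuple(errors), warnings=tuple(warnings))


def records_to_frame(
    records: Sequence[PatientRecord], schema: FeatureSchema
) -> pd.DataFrame:
    cols: dict[str, list] = {name: [] for name in schema.decision_inputs}
    for rec in records:
        for name in schema.decision_inputs:
            cols[name].append(rec.values.get(name, ""))
    frame = pd.DataFrame(cols)
    frame[schema.ca_feature] = [str(r.ca_performed) for r in records]
    frame[schema.hospital_field] = [r.hospital_id for r in records]
    frame[schema.outcome_field] = [str(r.outcome_class) for r in records]
    return frame


def frame_to_records(
    frame: pd.DataFrame, schema: FeatureSchema
) -> list[PatientRecord]:
    records = []
    dec = list(schema.decision_inputs)
    for row in frame.itertuples(index=False):
        d = dict(zip(frame.columns, row))
        records.append(
            PatientRecord(
                values={name: str(d[name]) for name in dec},
                hospital_id=str(d[schema.hospital_field]),
                ca_performed=int(d[schema.ca_feature]),
                outcome_class=int(d[schema.outcome_field]),
            )
        )
    return records


def write_registry(
    records: Sequence[PatientRecord], schema: FeatureSchema, path: str
) -> None:
    """Write a registry as UTF-8 CSV: features, CA, hospital, outcome.

    Level strings are stored verbatim so files stay human-auditable; binary
    fields serialize as "0"/"1".
    """
    records_to_frame(records, schema).to_csv(path, index=False)


def read_registry(path: str, schema: FeatureSchema) -> list[PatientRecord]:
    """Read a CSV registry; raises on missing columns or unknown levels."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = (
        list(schema.decision_inputs)
        + [schema.ca_feature, schema.hospital_field, schema.outcome_field]
    )
    missing = [c for c in expected if c not in frame.columns]
    if missing:
        raise ValueError(f"registry file {path} missing columns: {missing}")
    records = frame_to_records(frame[expected], schema)
    report = validate_registry(records, schema)
    if not report.ok:
        raise ValueError(
            "registry failed validation: " + "; ".join(report.errors[:10])
        )
    return records


@dataclass(frozen=True)
class DataSplit:
    """Disjoint, exhaustive assignment of record indices to the four sets."""

    assignment: tuple[str, ...]
    proportions: tuple[float, float, float, float]
    seed: int

    def __post_init__(self) -> None:
        bad = set(self.assignment) - set(SPLIT_NAMES)
        if bad:
            raise ValueError(f"unknown split names: {sorted(bad)}")

    def indices(self, name: str) -> list[int]:
        if name not in SPLIT_NAMES:
            raise KeyError(name)
        return [i for i, s in enumerate(self.assignment) if s == name]

    def subset(self, records: Sequence, name: str) -> list:
        return [records[i] for i in self.indices(name)]

    def sizes(self) -> dict[str, int]:
        return {name: len(self.indices(name)) for name in SPLIT_NAMES}

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(
                {
                    "assignment": list(self.assignment),
                    "proportions": list(self.proportions),
                    "seed": self.seed,
                },
                fh,
            )

    @classmethod
    def from_json(cls, path: str) -> "DataSplit":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        return cls(
            assignment=tuple(payload["assignment"]),
            proportions=tuple(payload["proportions"]),
            seed=payload["seed"],
        )


def largest_remainder_sizes(n: int, proportions: Sequence[float]) -> list[int]:
    """Apportion ``n`` into integer sizes by largest-remainder rounding.

    Floors first, then hands the leftover units to the largest fractional
    remainders; ties go to the earlier split in declaration order.
    """
    exact = [p * n for p in proportions]
    sizes = [int(e) for e in exact]
    leftover = n - sum(sizes)
    remainders = sorted(
        range(len(proportions)), key=lambda i: (-(exact[i] - sizes[i]), i)
    )
    for i in remainders[:leftover]:
        sizes[i] += 1
    return sizes


def split_data(
    records: Sequence,
    proportions: Sequence[float] = (0.40, 0.10, 0.25, 0.25),
    seed: int = 0,
) -> DataSplit:
    """Randomly partition records into train/validation/test/cohort-analysis.

    Assignment is simple random (no stratification by outcome or hospital),
    deterministic given ``seed``; realized sizes follow largest-remainder
    rounding of the proportions.
    """
    import numpy as np

    n = len(records)
    if n == 0:
        raise ValueError("cannot split an empty record list")
    if len(proportions) != 4:
        raise ValueError("exactly four proportions required")
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    sizes = largest_remainder_sizes(n, proportions)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignment = [""] * n
    start = 0
    for name, size in zip(SPLIT_NAMES, sizes):
        for idx in order[start : start + size]:
            assignment[idx] = name
        start += size
    return DataSplit(
        assignment=tuple(assignment),
        proportions=tuple(float(p) for p in proportions),
        seed=seed,
    )


def labels(
    records: Sequence[PatientRecord], task: Literal["decision", "outcome"]
) -> "list[int]":
    """Binary labels for a task: CA performed, or outcome Class 1."""
    if task == "decision":
        return [r.ca_performed for r in records]
    if task == "outcome":
        return [r.outcome_class for r in records]
    raise ValueError(f"unknown task {task!r}")
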