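"""Categorical record encodings: one-hot for classical models, integer
level indices for embedding models.

Column/row order always follows the schema (feature order, then level order),
never data frequency — a stable layout is what makes transferring embedding
tables between the decision and survival models meaningful.  The survival
input set appends the CA feature as the final column.  All levels are kept
(no reference-level drop), matching the registry's closed vocabulary; an
unknown level is an error unless ``permissive=True`` maps it to the feature's
first level with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from postrosc.data_model import FeatureSchema, InputSet, PatientRecord


def _record_level(rec: PatientRecord, schema: FeatureSchema, name: str) -> str:
    if name == schema.ca_feature:
        return str(rec.ca_performed)
    try:
        return rec.values[name]
    except KeyError:
        raise ValueError(f"record missing feature {name!r}") from None


@dataclass(frozen=True)
class EncodedMatrix:
    """One-hot encoded registry: n_records x sum(level counts) of {0,1}."""

    matrix: np.ndarray
    column_map: tuple[tuple[str, str], ...]  # (feature, level) per column
    feature_offsets: dict[str, tuple[int, int]]  # feature -> [start, stop)

    def decode(self, schema: FeatureSchema) -> list[dict[str, str]]:
        out = []
        for row in self.matrix:
            values = {}
            for name, (start, stop) in self.feature_offsets.items():
                idx = int(np.argmax(row[start:stop]))
                values[name] = schema.levels(name)[idx]
            out.append(values)
        return out

    def header(self) -> list[str]:
        return [f"{f}={lvl}" for f, lvl in self.column_map]


@dataclass(frozen=True)
class IndexMatrix:
    """Level-index encoded registry: n_records x n_features of ints."""

    matrix: np.ndarray
    features: tuple[str, ...]
    level_dictionaries: tuple[dict[str, int], ...]

    @property
    def level_counts(self) -> tuple[int, ...]:
        return tuple(len(d) for d in self.level_dictionaries)

    def decode(self) -> list[dict[str, str]]:
        inverse = [{i: lvl for lvl, i in d.items()} for d in self.level_dictionaries]
        return [
            {
                name: inverse[j][int(row[j])]
                for j, name in enumerate(self.features)
            }
            for row in self.matrix
        ]


def _level_index(
    rec_i: int,
    rec: PatientRecord,
    schema: FeatureSchema,
    name: str,
    lookup: dict[str, int],
    permissive: bool,
) -> int:
    level = _record_level(rec, schema, name)
    idx = lookup.get(level)
    if idx is None:
        if permissive:
            warnings.warn(
                f"record {rec_i}: unknown level {level!r} for {name!r}; "
                "mapped to the feature's first level",
                stacklevel=3,
            )
            return 0
        raise ValueError(
            f"record {rec_i}: unknown level {level!r} for feature {name!r}"
        )
    return idx


def index_encode(
    records: Sequence[PatientRecord],
    schema: FeatureSchema,
    input_set: InputSet = "decision",
    permissive: bool = False,
) -> IndexMatrix:
    """Encode records as per-feature level indices (schema level order)."""
    features = schema.inputs(input_set)
    lookups = tuple(
        {lvl: i for i, lvl in enumerate(schema.levels(name))} for name in features
    )
    matrix = np.empty((len(records), len(features)), dtype=np.int64)
    for i, rec in enumerate(records):
        for j, name in enumerate(features):
            matrix[i, j] = _level_index(i, rec, schema, name, lookups[j], permissive)
    return IndexMatrix(matrix=matrix, features=features, level_dictionaries=lookups)


def one_hot_encode(
    records: Sequence[PatientRecord],
    schema: FeatureSchema,
    input_set: InputSet = "decision",
    permissive: bool = False,
) -> EncodedMatrix:
    """Encode records as a dense {0,1} indicator matrix.

    Each feature occupies a contiguous block of columns, one per level in
    schema order; exactly one column per block is hot.  E.g. a CPR-initiation
    feature with levels (lay_person, first_responder, ems_personnel) encodes a
    first-responder record as the block [0, 1, 0].
    """
    idx = index_encode(records, schema, input_set, permissive)
    features = idx.features
    counts = idx.level_counts
    offsets: dict[str, tuple[int, int]] = {}
    column_map: list[tuple[str, str]] = []
    start = 0
    for name, k in zip(features, counts):
        offsets[name] = (start, start + k)
        column_map.extend((name, lvl) for lvl in schema.levels(name))
        start += k
    matrix = np.zeros((len(records), start), dtype=np.int8)
    starts = np.array([offsets[name][0] for name in features])
    cols = idx.matrix + starts[None, :]
    rows = np.repeat(np.arange(len(records)), len(features))
    matrix[rows, cols.ravel()] = 1
    return EncodedMatrix(
        matrix=matrix,
        column_map=tuple(column_map),
        feature_offsets=offsets,
    )


def indices_to_one_hot(idx: IndexMatrix) -> np.ndarray:
    """Expand an IndexMatrix to the indicator layout of one_hot_encode."""
    counts = idx.level_counts
    total = sum(counts)
    starts = np.cumsum([0] + list(counts[:-1]))
    matrix = np.zeros((len(idx.matrix), total), dtype=np.int8)
    cols = idx.matrix + starts[None, :]
    rows = np.repeat(np.arange(len(idx.matrix)), len(counts))
    matrix[rows, cols.ravel()] = 1
    return matrix
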