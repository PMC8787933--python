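"""Hospital-cohort stratification and the counterfactual care audit.

Hospitals with enough study patients are ranked by their CPC 1/2 (functional
outcome, Class 0) rate on the combined training + validation instances and
grouped best-to-worst into equal-size cohorts (5-5-5 tertiles by default).
The decision/survival model pair is fine-tuned on the best cohort's data and
then audits each worse cohort's held-out patients: for every patient who did
NOT receive coronary angiography (CA), the best-cohort decision model says
whether it would have provided one; for those flipped decisions the survival
model is scored under both CA values to classify the predicted outcome
change (positive = non-functional -> functional, i.e. Class 1 -> 0).

The audit is purely predictive re-scoring — no causal adjustment is applied,
mirroring the registry analysis it reproduces.  Only the CA=0 -> CA=1
direction is audited; patients who received CA are never counterfactually
denied it.  Uncertainty is quantified by a percentile bootstrap over
patients within the target cohort.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from postrosc.data_model import DataSplit, FeatureSchema, PatientRecord
from postrosc.efcn import EFCN, EFCNBundle, TrainConfig, train_efcn


@dataclass(frozen=True)
class CohortAssignment:
    """Best-to-worst hospital cohorts with provenance of exclusions."""

    cohorts: tuple[tuple[str, ...], ...]
    cpc12_rates: tuple[float, ...]
    excluded_hospitals: dict[str, str]
    min_instances: int
    hospitals_per_cohort: int

    def cohort_of(self, hospital_id: str) -> Optional[int]:
        """0-based cohort index (0 = best), or None if excluded."""
        for i, members in enumerate(self.cohorts):
            if hospital_id in members:
                return i
        return None


def assign_cohorts(
    records: Sequence[PatientRecord],
    min_instances: int = 75,
    hospitals_per_cohort: int = 5,
    n_cohorts: int = 3,
    volume_records: Optional[Sequence[PatientRecord]] = None,
) -> CohortAssignment:
    """Rank qualifying hospitals by CPC1/2 rate and cut into cohorts.

    ``records`` should be the combined train+validation instances; the CPC1/2
    rates are always computed on them.  The volume threshold, however, refers
    to a hospital's instances over the whole study period, so pass the full
    registry as ``volume_records`` (defaults to ``records``).  Hospitals
    with fewer than ``min_instances`` volume records are excluded; qualifying
    hospitals are ordered by Class-0 rate (descending), ties broken by larger
    volume then lexical id, and the top ``hospitals_per_cohort`` form
    Cohort 1, the next block Cohort 2, and so on.  Qualifying hospitals
    beyond ``n_cohorts * hospitals_per_cohort`` are excluded with a recorded
    reason.
    """
    counts: dict[str, int] = {}
    class0: dict[str, int] = {}
    for rec in records:
        counts[rec.hospital_id] = counts.get(rec.hospital_id, 0) + 1
        class0[rec.hospital_id] = class0.get(rec.hospital_id, 0) + (
            1 - rec.outcome_class
        )
    volumes: dict[str, int] = {}
    for rec in volume_records if volume_records is not None else records:
        volumes[rec.hospital_id] = volumes.get(rec.hospital_id, 0) + 1
    excluded = {
        h: f"volume {volumes.get(h, 0)} < min_instances {min_instances}"
        for h in set(volumes) | set(counts)
        if volumes.get(h, 0) < min_instances
    }
    qualifying = [h for h in counts if h not in excluded]
    needed = n_cohorts * hospitals_per_cohort
    if len(qualifying) < needed:
        raise ValueError(
            f"only {len(qualifying)} hospitals with >= {min_instances} "
            f"instances; {needed} required for {n_cohorts} cohorts of "
            f"{hospitals_per_cohort}"
        )
    ranked = sorted(
        qualifying,
        key=lambda h: (-class0[h] / counts[h], -counts[h], h),
    )
    for h in ranked[needed:]:
        excluded[h] = "qualifying but beyond cohort capacity"
    ranked = ranked[:needed]
    cohorts = tuple(
        tuple(ranked[i * hospitals_per_cohort : (i + 1) * hospitals_per_cohort])
        for i in range(n_cohorts)
    )
    rates = tuple(
        sum(class0[h] for h in members) / sum(counts[h] for h in members)
        for members in cohorts
    )
    return CohortAssignment(
        cohorts=cohorts,
        cpc12_rates=rates,
        excluded_hospitals=excluded,
        min_instances=min_instances,
        hospitals_per_cohort=hospitals_per_cohort,
    )


def retrain_on_cohort(
    bundle: EFCNBundle,
    cohort_train: Sequence[PatientRecord],
    cohort_validation: Sequence[PatientRecord],
    schema: FeatureSchema,
    hyper: Optional[TrainConfig] = None,
) -> EFCNBundle:
    """Fine-tune the full-data model pair on one cohort's data.

    Both networks start from the full-data weights (never from random
    re-initialization) and re-optimize on the cohort's training instances
    with early stopping on the cohort's validation instances.  The input
    bundle is deep-copied and never modified.  ``max_epochs=0`` returns the
    full-data models unchanged (the identity limit).
    """
    from postrosc.data_model import labels
    from postrosc.encoding import index_encode

    hyper = hyper or TrainConfig()
    tuned = bundle.clone()
    if hyper.max_epochs == 0:
        return tuned
    Xtr_d = index_encode(cohort_train, schema, "decision")
    Xva_d = index_encode(cohort_validation, schema, "decision")
    hist_d = train_efcn(
        tuned.decision_model,
        (Xtr_d, labels(cohort_train, "decision")),
        (Xva_d, labels(cohort_validation, "decision")),
        hyper,
    )
    Xtr_s = index_encode(cohort_train, schema, "survival")
    Xva_s = index_encode(cohort_validation, schema, "survival")
    hist_s = train_efcn(
        tuned.survival_model,
        (Xtr_s, labels(cohort_train, "outcome")),
        (Xva_s, labels(cohort_validation, "outcome")),
        hyper,
    )
    tuned.training_history["cohort_decision"] = hist_d
    tuned.training_history["cohort_survival"] = hist_s
    return tuned


@dataclass(frozen=True)
class CounterfactualTable:
    """Audit counts for one target cohort.

    Accounting identity: ``n_flipped_to_ca = n_no_change + n_positive_change
    + n_negative_change`` and ``n_flipped_to_ca <= n_no_initial_ca <=
    n_total``.
    """

    cohort_label: str
    n_total: int
    n_no_initial_ca: int
    n_flipped_to_ca: int
    n_no_change: int
    n_positive_change: int
    n_negative_change: int
    threshold: float
    survival_model_source: str = "cohort1_finetuned"

    def __post_init__(self) -> None:
        if self.n_flipped_to_ca != (
            self.n_no_change + self.n_positive_change + self.n_negative_change
        ):
            raise ValueError("change counts must sum to flipped count")
        if not (
            0
            <= self.n_flipped_to_ca
            <= self.n_no_initial_ca
            <= self.n_total
        ):
            raise ValueError("count ordering violated")

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort_label,
            "n_total": self.n_total,
            "n_no_initial_ca": self.n_no_initial_ca,
            "n_flipped_to_ca": self.n_flipped_to_ca,
            "n_no_change": self.n_no_change,
            "n_positive_change": self.n_positive_change,
            "n_negative_change": self.n_negative_change,
            "threshold": self.threshold,
            "survival_model_source": self.survival_model_source,
        }


def counterfactual_audit(
    cohort1_bundle: EFCNBundle,
    target_records: Sequence[PatientRecord],
    schema: FeatureSchema,
    threshold: float = 0.5,
    cohort_label: str = "",
    split: Optional[DataSplit] = None,
    registry: Optional[Sequence[PatientRecord]] = None,
) -> CounterfactualTable:
    """Audit one target cohort's CA decisions with the best-cohort models.

    For each target patient with ``ca_performed = 0``: the decision model's
    score at or above ``threshold`` flips the decision to "provide CA"; for
    flipped patients the survival model is scored under CA=0 and CA=1 and
    each score classified at the same threshold.  A predicted move from
    Class 1 to Class 0 is a positive change (non-functional -> functional),
    the reverse negative, otherwise no change.

    If ``split`` and ``registry`` are given, every target record is asserted
    to be a cohort-analysis row (leakage guard).
    """
    from postrosc.encoding import index_encode

    if split is not None and registry is not None:
        allowed = {id(registry[i]) for i in split.indices("cohort_analysis")}
        for rec in target_records:
            if id(rec) not in allowed:
                raise ValueError(
                    "target record outside the cohort-analysis split "
                    "(leakage guard)"
                )
    n_total = len(target_records)
    no_ca = [r for r in target_records if r.ca_performed == 0]
    if not no_ca:
        warnings.warn("no records without initial CA in target cohort", stacklevel=2)
        return CounterfactualTable(
            cohort_label=cohort_label,
            n_total=n_total,
            n_no_initial_ca=0,
            n_flipped_to_ca=0,
            n_no_change=0,
            n_positive_change=0,
            n_negative_change=0,
            threshold=threshold,
        )
    X_dec = index_encode(no_ca, schema, "decision")
    dec_scores = cohort1_bundle.decision_model.predict(X_dec)
    flipped = [r for r, s in zip(no_ca, dec_scores) if s >= threshold]
    n_pos = n_neg = n_none = 0
    if flipped:
        import dataclasses

        flipped_ca0 = flipped
        flipped_ca1 = [dataclasses.replace(r, ca_performed=1) for r in flipped]
        s0 = cohort1_bundle.survival_model.predict(
            index_encode(flipped_ca0, schema, "survival")
        )
        s1 = cohort1_bundle.survival_model.predict(
            index_encode(flipped_ca1, schema, "survival")
        )
        cls0 = (s0 >= threshold).astype(int)  # predicted class under CA=0
        cls1 = (s1 >= threshold).astype(int)  # predicted class under CA=1
        n_pos = int(np.sum((cls0 == 1) & (cls1 == 0)))
        n_neg = int(np.sum((cls0 == 0) & (cls1 == 1)))
        n_none = len(flipped) - n_pos - n_neg
    return CounterfactualTable(
        cohort_label=cohort_label,
        n_total=n_total,
        n_no_initial_ca=len(no_ca),
        n_flipped_to_ca=len(flipped),
        n_no_change=n_none,
        n_positive_change=n_pos,
        n_negative_change=n_neg,
        threshold=threshold,
    )


def percentage(numerator: int, denominator: int, decimals: int = 2) -> Optional[float]:
    """100 * numerator / denominator, half-up rounded; None when 0/0."""
    if denominator == 0:
        return None
    frac = Decimal(100 * numerator) / Decimal(denominator)
    q = Decimal(1).scaleb(-decimals)
    return float(frac.quantize(q, rounding=ROUND_HALF_UP))


def summarize_table(
    table: CounterfactualTable,
    decimals_map: Optional[dict[str, int]] = None,
) -> dict[str, dict]:
    """Rendered audit rows: count fraction strings plus derived percentages.

    Default rounding: the flip rate at two decimals, the change rates at one —
    the registry table's own convention.  Zero denominators render as
    ``None`` percentages.
    """
    decimals = {"flip": 2, "change": 1}
    if decimals_map:
        decimals.update(decimals_map)
    t = table
    rows = {
        "predicted_to_get_ca": (t.n_flipped_to_ca, t.n_no_initial_ca, decimals["flip"]),
        "no_change_in_cpc_class": (t.n_no_change, t.n_flipped_to_ca, decimals["change"]),
        "positive_change_in_cpc_class": (
            t.n_positive_change,
            t.n_flipped_to_ca,
            decimals["change"],
        ),
        "negative_change_in_cpc_class": (
            t.n_negative_change,
            t.n_flipped_to_ca,
            decimals["change"],
        ),
    }
    out = {}
    for name, (num, den, dec) in rows.items():
        pct = percentage(num, den, dec)
        out[name] = {
            "fraction": f"{num}/{den}",
            "percent": pct,
            "rendered": f"{num}/{den} ({'undefined' if pct is None else _trim(pct)}%)",
        }
    return out


def _trim(x: float) -> str:
    s = f"{x:f}".rstrip("0").rstrip(".")
    return s if s else "0"


@dataclass(frozen=True)
class IntervalEstimate:
    point: float
    lower: float
    upper: float
    method: str
    replicates: int
    seed: int

    def __post_init__(self) -> None:
        if not self.lower <= self.point <= self.upper:
            raise ValueError("interval must contain the point estimate")


STATISTICS = ("flip_rate", "positive_change_rate")


def _statistic_from_table(table: CounterfactualTable, statistic: str) -> Optional[float]:
    if statistic == "flip_rate":
        if table.n_no_initial_ca == 0:
            return None
        return table.n_flipped_to_ca / table.n_no_initial_ca
    if statistic == "positive_change_rate":
        if table.n_flipped_to_ca == 0:
            return None
        return table.n_positive_change / table.n_flipped_to_ca
    raise ValueError(f"unknown statistic {statistic!r}")


def bootstrap_ci(
    audit: Callable[[Sequence[PatientRecord]], CounterfactualTable],
    target_records: Sequence[PatientRecord],
    statistic: str = "flip_rate",
    replicates: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> IntervalEstimate:
    """Percentile bootstrap over patient resampling within the target set.

    Degenerate resamples (undefined statistic, e.g. no CA=0 patients) are
    skipped and counted; a warning is issued if more than 1% are skipped.
    Deterministic given ``seed``.
    """
    if replicates < 100:
        raise ValueError("at least 100 bootstrap replicates required")
    point = _statistic_from_table(audit(target_records), statistic)
    if point is None:
        raise ValueError("statistic undefined on the full target set")
    rng = np.random.default_rng(seed)
    n = len(target_records)
    values = []
    skipped = 0
    for _ in range(replicates):
        idx = rng.integers(0, n, size=n)
        sample = [target_records[i] for i in idx]
        val = _statistic_from_table(audit(sample), statistic)
        if val is None:
            skipped += 1
        else:
            values.append(val)
    if skipped > 0.01 * replicates:
        warnings.warn(
            f"{skipped}/{replicates} bootstrap resamples degenerate", stacklevel=2
        )
    alpha = 1.0 - level
    lower, upper = np.quantile(values, [alpha / 2, 1 - alpha / 2])
    return IntervalEstimate(
        point=float(point),
        lower=float(min(lower, point)),
        upper=float(max(upper, point)),
        method=f"percentile bootstrap, patient resampling, level {level}",
        replicates=replicates,
        seed=seed,
    )


def percentile_proportion_ci(
    outcomes: np.ndarray, replicates: int = 1000, seed: int = 0, level: float = 0.95
) -> tuple[float, float, float]:
    """Vectorized percentile bootstrap CI for a simple proportion.

    The same estimator ``bootstrap_ci`` applies to audit statistics, exposed
    directly for binary outcomes so coverage can be simulated cheaply.
    Returns (point, lower, upper).
    """
    y = np.asarray(outcomes)
    rng = np.random.default_rng(seed)
    n = len(y)
    idx = rng.integers(0, n, size=(replicates, n))
    means = y[idx].mean(axis=1)
    alpha = 1.0 - level
    lower, upper = np.quantile(means, [alpha / 2, 1 - alpha / 2])
    return float(y.mean()), float(lower), float(upper)
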