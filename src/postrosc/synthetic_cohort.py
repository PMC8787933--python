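"""Synthetic OHCA registry generator with latent-truth sidecar.

The generator emulates the statistical structure of an admitted-after-ROSC
cardiac-arrest registry: all-categorical covariates, a hospital-level
coronary-angiography (CA) decision policy, and a neurologic outcome that
depends on the covariates, on the CA decision, and on hospital quality.

Sampling order per patient (all log-odds additive, logistic link):

1. hospital ~ volume weights,
2. covariates ~ independent per-feature marginals (a joint-sampler hook is
   available for dependence),
3. CA ~ Bernoulli(sigmoid(decision linear predictor + hospital decision
   offset)),
4. outcome Class 1 ~ Bernoulli(sigmoid(outcome linear predictor
   + ca_outcome_effect * CA + hospital quality offset)).

Because the true per-patient probabilities are retained in a sidecar, the
Bayes-optimal AUROC of each task is computable and serves as the ceiling
against which trained models are judged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from postrosc.data_model import FeatureSchema, PatientRecord

# Default schema: 23 categorical decision inputs typical of a US cardiac
# arrest registry, plus the CA feature consumed only by the outcome model.
# The TTM-related input is included as a covariate (an assumption; TTM is
# never modeled as a decision).
_DEFAULT_FEATURES: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("age_group", ("18-40", "41-60", "61-80", "81plus")),
    ("sex", ("female", "male", "unknown")),
    ("race_ethnicity", ("black", "hispanic", "white", "other")),
    ("arrest_witnessed", ("unwitnessed", "bystander_witnessed", "ems_witnessed")),
    ("location_type", ("home", "public", "healthcare_facility")),
    ("initial_rhythm", ("vf_vt", "pea", "asystole", "unknown_shockable")),
    ("etiology", ("presumed_cardiac", "respiratory", "other")),
    ("bystander_cpr", ("none", "compression_only", "full_cpr")),
    ("cpr_initiation", ("lay_person", "first_responder", "ems_personnel")),
    ("aed_before_ems", ("not_applied", "applied_no_shock", "applied_shock")),
    ("ems_response_interval", ("0-4min", "5-8min", "9plus_min")),
    ("prehospital_defibrillation", ("none", "single_shock", "multiple_shocks")),
    ("prehospital_epinephrine", ("none", "single_dose", "multiple_doses")),
    ("prehospital_antiarrhythmic", ("none", "amiodarone", "lidocaine")),
    ("airway_management", ("bvm_only", "supraglottic", "endotracheal")),
    ("rosc_timing", ("field_early", "field_late", "ed_arrival")),
    ("prehospital_12lead", ("not_obtained", "obtained_normal", "obtained_stemi")),
    ("mechanical_cpr_device", ("none", "load_distributing_band", "piston_device")),
    ("transport_interval", ("0-9min", "10-19min", "20plus_min")),
    ("day_period", ("day", "evening", "night")),
    ("comatose_on_arrival", ("yes", "no", "sedated_unknown")),
    ("ttm_induction", ("none", "initiated_prehospital", "initiated_hospital")),
    ("destination_capability", ("non_stemi_center", "stemi_center", "stemi_center_pci24")),
)

CA_FEATURE = "coronary_angiography"

DEFAULT_CA_RATE = 0.215
DEFAULT_CLASS0_RATE = 0.208


def default_schema() -> FeatureSchema:
    """23 decision inputs plus the CA feature (outcome-model input only)."""
    features = _DEFAULT_FEATURES + ((CA_FEATURE, ("0", "1")),)
    return FeatureSchema(
        features=features,
        decision_inputs=tuple(n for n, _ in _DEFAULT_FEATURES),
        ca_feature=CA_FEATURE,
    )


@dataclass
class GeneratorConfig:
    """Latent logistic model of a registry.

    ``decision_coeffs`` / ``outcome_coeffs`` map feature -> per-level log-odds
    contributions (arrays aligned with the schema's level order, centered to
    mean 0 under the marginals).  Hospital effects enter as additive log-odds
    offsets: ``hospital_decision_offsets`` shifts CA propensity,
    ``hospital_quality_offsets`` shifts Class-1 (non-functional outcome)
    probability — negative quality offset means a better hospital.
    ``ca_outcome_effect`` is the log-odds effect of CA on Class 1; negative
    means CA improves outcomes.
    """

    schema: FeatureSchema
    n_patients: int
    hospital_ids: tuple[str, ...]
    hospital_volume_weights: np.ndarray
    covariate_marginals: dict[str, np.ndarray]
    decision_coeffs: dict[str, np.ndarray]
    decision_intercept: float
    hospital_decision_offsets: np.ndarray
    outcome_coeffs: dict[str, np.ndarray]
    outcome_intercept: float
    ca_outcome_effect: float
    hospital_quality_offsets: np.ndarray
    seed: int
    calibrated: bool = False
    covariate_sampler: Optional[Callable[[np.random.Generator, int], np.ndarray]] = None

    def __post_init__(self) -> None:
        w = np.asarray(self.hospital_volume_weights, dtype=float)
        if abs(w.sum() - 1.0) > 1e-9:
            raise ValueError("hospital_volume_weights must sum to 1")
        if len(self.hospital_ids) != len(w):
            raise ValueError("one volume weight per hospital required")
        for name, probs in self.covariate_marginals.items():
            p = np.asarray(probs, dtype=float)
            if abs(p.sum() - 1.0) > 1e-9:
                raise ValueError(f"marginals for {name!r} must sum to 1")
            if len(p) != len(self.schema.levels(name)):
                raise ValueError(f"marginals for {name!r} wrong length")

    @property
    def n_hospitals(self) -> int:
        return len(self.hospital_ids)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    e = np.exp(x[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def default_config(
    n_patients: int = 2398,
    seed: int = 0,
    ca_rate: float = DEFAULT_CA_RATE,
    class0_rate: float = DEFAULT_CLASS0_RATE,
    calibrate: bool = True,
) -> GeneratorConfig:
    """Ready-to-use registry model mirroring the study's marginal structure.

    33 hospitals with heterogeneous volumes (15 high-volume hospitals that
    clear a 75-instance threshold at n=2398, 18 low-volume ones that do not),
    23 covariates with mildly non-uniform marginals, covariate effects with
    decaying strength on both tasks, a beneficial CA effect on outcome, and
    hospital decision policy positively correlated with hospital quality
    (better hospitals perform CA more readily).  Intercepts are calibrated so
    the marginal CA rate is ~21.5% and the functional-outcome (Class 0) rate
    ~20.8%.
    """
    schema = default_schema()
    rng = np.random.default_rng(np.random.SeedSequence([987_654_321, seed]))

    n_hosp = 33
    n_large = 15
    hospital_ids = tuple(f"H{i + 1:02d}" for i in range(n_hosp))
    raw = np.concatenate(
        [np.linspace(1.0, 1.8, n_large), np.full(n_hosp - n_large, 0.085)]
    )
    volume_weights = raw / raw.sum()

    marginals: dict[str, np.ndarray] = {}
    for name in schema.decision_inputs:
        k = len(schema.levels(name))
        alpha = rng.uniform(1.5, 4.0, size=k)
        marginals[name] = alpha / alpha.sum()

    def draw_coeffs(scales: np.ndarray) -> dict[str, np.ndarray]:
        coeffs = {}
        for j, name in enumerate(schema.decision_inputs):
            k = len(schema.levels(name))
            c = rng.normal(0.0, 1.0, size=k) * scales[j]
            c -= c @ marginals[name]  # center under the marginal
            coeffs[name] = c
        return coeffs

    # Decaying effect strengths: a handful of strong predictors (rhythm,
    # witnessed status, CPR...) and a tail of weak ones.  Chosen so the
    # Bayes-optimal AUROC of both tasks sits in the high-0.8s, comparable to
    # a well-specified registry model.
    order = rng.permutation(len(schema.decision_inputs))
    scales_dec = 1.5 * np.exp(-order / 7.0)
    order2 = rng.permutation(len(schema.decision_inputs))
    scales_out = 1.5 * np.exp(-order2 / 7.0)
    decision_coeffs = draw_coeffs(scales_dec)
    outcome_coeffs = draw_coeffs(scales_out)

    quality = rng.normal(0.0, 0.7, size=n_hosp)
    decision_off = -1.3 * quality + rng.normal(0.0, 0.25, size=n_hosp)
    # negative quality offset = better hospital; better hospitals lean toward
    # providing CA, so decision offsets are anti-correlated with quality
    # offsets (positively correlated with quality itself).
    quality -= quality @ volume_weights
    decision_off -= decision_off @ volume_weights

    config = GeneratorConfig(
        schema=schema,
        n_patients=n_patients,
        hospital_ids=hospital_ids,
        hospital_volume_weights=volume_weights,
        covariate_marginals=marginals,
        decision_coeffs=decision_coeffs,
        decision_intercept=0.0,
        hospital_decision_offsets=decision_off,
        outcome_coeffs=outcome_coeffs,
        outcome_intercept=0.0,
        ca_outcome_effect=-1.3,
        hospital_quality_offsets=quality,
        seed=seed,
    )
    if calibrate:
        config = calibrate_intercepts(config, ca_rate, class0_rate)
    return config


def _sample_levels(
    config: GeneratorConfig, rng: np.random.Generator, n: int
) -> np.ndarray:
    """n x n_features matrix of level indices."""
    if config.covariate_sampler is not None:
        X = np.asarray(config.covariate_sampler(rng, n))
        if X.shape != (n, len(config.schema.decision_inputs)):
            raise ValueError("covariate_sampler returned wrong shape")
        return X
    cols = []
    for name in config.schema.decision_inputs:
        p = config.covariate_marginals[name]
        cols.append(np.searchsorted(np.cumsum(p), rng.random(n)))
    return np.column_stack(cols)


def _linear_predictor(
    config: GeneratorConfig, X: np.ndarray, coeffs: dict[str, np.ndarray]
) -> np.ndarray:
    lp = np.zeros(len(X))
    for j, name in enumerate(config.schema.decision_inputs):
        lp += coeffs[name][X[:, j]]
    return lp


def calibrate_intercepts(
    config: GeneratorConfig,
    target_ca_rate: float = DEFAULT_CA_RATE,
    target_class0_rate: float = DEFAULT_CLASS0_RATE,
    n_mc: int = 100_000,
) -> GeneratorConfig:
    """Solve for intercepts matching the target marginal rates.

    Monte-Carlo estimate of each marginal on a fixed draw of covariates and
    hospitals (common random numbers), then monotone 1-D root finding on the
    intercept.  The decision intercept is solved first; the outcome marginal
    then averages over the CA propensity rather than a CA realization, so the
    second root-find is smooth and deterministic.
    """
    for t in (target_ca_rate, target_class0_rate):
        if not 0.0 < t < 1.0:
            raise ValueError(f"target rate {t} outside (0, 1)")
    rng = np.random.default_rng(np.random.SeedSequence([123_456_789, config.seed]))
    X = _sample_levels(config, rng, n_mc)
    hosp = rng.choice(config.n_hospitals, size=n_mc, p=config.hospital_volume_weights)

    lp_dec = _linear_predictor(config, X, config.decision_coeffs)
    lp_dec += config.hospital_decision_offsets[hosp]

    def ca_gap(b: float) -> float:
        return float(_sigmoid(b + lp_dec).mean() - target_ca_rate)

    try:
        b_dec = brentq(ca_gap, -30.0, 30.0, xtol=1e-10)
    except ValueError as exc:  # pragma: no cover - pathological coefficients
        raise ValueError("CA target rate not bracketable") from exc

    p_ca = _sigmoid(b_dec + lp_dec)
    lp_out = _linear_predictor(config, X, config.outcome_coeffs)
    lp_out += config.hospital_quality_offsets[hosp]
    target_class1 = 1.0 - target_class0_rate

    def out_gap(b: float) -> float:
        p1 = p_ca * _sigmoid(b + lp_out + config.ca_outcome_effect)
        p0 = (1.0 - p_ca) * _sigmoid(b + lp_out)
        return float((p1 + p0).mean() - target_class1)

    try:
        b_out = brentq(out_gap, -30.0, 30.0, xtol=1e-10)
    except ValueError as exc:  # pragma: no cover
        raise ValueError("outcome target rate not bracketable") from exc

    return replace(
        config,
        decision_intercept=float(b_dec),
        outcome_intercept=float(b_out),
        calibrated=True,
    )


def generate(
    config: GeneratorConfig,
    n_patients: Optional[int] = None,
    seed: Optional[int] = None,
) -> tuple[list[PatientRecord], pd.DataFrame]:
    """Sample a registry and its latent-truth sidecar.

    The sidecar holds, per patient, the exact probabilities used in sampling:
    ``p_ca`` (true CA propensity), ``p_class1_ca0`` / ``p_class1_ca1``
    (Class-1 probability under either CA value) and the realized labels.
    Deterministic given the seed.
    """
    if not config.calibrated:
        warnings.warn("generating from an uncalibrated config", stacklevel=2)
    n = config.n_patients if n_patients is None else n_patients
    rng = np.random.default_rng(config.seed if seed is None else seed)

    hosp = rng.choice(config.n_hospitals, size=n, p=config.hospital_volume_weights)
    X = _sample_levels(config, rng, n)

    p_ca = _sigmoid(
        config.decision_intercept
        + _linear_predictor(config, X, config.decision_coeffs)
        + config.hospital_decision_offsets[hosp]
    )
    ca = (rng.random(n) < p_ca).astype(int)

    lp_out = (
        config.outcome_intercept
        + _linear_predictor(config, X, config.outcome_coeffs)
        + config.hospital_quality_offsets[hosp]
    )
    p1_ca0 = _sigmoid(lp_out)
    p1_ca1 = _sigmoid(lp_out + config.ca_outcome_effect)
    p1 = np.where(ca == 1, p1_ca1, p1_ca0)
    outcome = (rng.random(n) < p1).astype(int)

    schema = config.schema
    level_lists = [schema.levels(name) for name in schema.decision_inputs]
    records = [
        PatientRecord(
            values={
                name: level_lists[j][X[i, j]]
                for j, name in enumerate(schema.decision_inputs)
            },
            hospital_id=config.hospital_ids[hosp[i]],
            ca_performed=int(ca[i]),
            outcome_class=int(outcome[i]),
        )
        for i in range(n)
    ]
    sidecar = pd.DataFrame(
        {
            "hospital_id": [config.hospital_ids[h] for h in hosp],
            "p_ca": p_ca,
            "p_class1_ca0": p1_ca0,
            "p_class1_ca1": p1_ca1,
            "ca_performed": ca,
            "outcome_class": outcome,
        }
    )
    return records, sidecar


def bayes_auroc(sidecar: pd.DataFrame, task: str) -> float:
    """AUROC of the true generating probability against realized labels.

    This is the performance ceiling: no model can beat the true probability
    in expectation, so trained-model AUROCs are judged against it.
    """
    from postrosc.metrics import auroc

    if task == "decision":
        scores = sidecar["p_ca"].to_numpy()
        y = sidecar["ca_performed"].to_numpy()
    elif task == "outcome":
        ca = sidecar["ca_performed"].to_numpy()
        scores = np.where(
            ca == 1,
            sidecar["p_class1_ca1"].to_numpy(),
            sidecar["p_class1_ca0"].to_numpy(),
        )
        y = sidecar["outcome_class"].to_numpy()
    else:
        raise ValueError(f"unknown task {task!r}")
    return auroc(scores, y)
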