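"""Cohort stratification, fine-tuning, counterfactual audit, bootstrap."""

import dataclasses

import numpy as np
import pytest

from postrosc.cohort import (
    CounterfactualTable,
    assign_cohorts,
    bootstrap_ci,
    counterfactual_audit,
    percentage,
    retrain_on_cohort,
    summarize_table,
)
from postrosc.data_model import PatientRecord, split_data
from postrosc.efcn import EFCNArchitecture, EFCNBundle, TrainConfig, train_efcn_pair

from .conftest import make_toy_records, make_toy_schema
from .test_synthetic import flat_config


def hosp_records(hid, n_class0, n_class1, ca=0):
    recs = [
        PatientRecord({}, hid, ca, 0) for _ in range(n_class0)
    ] + [PatientRecord({}, hid, ca, 1) for _ in range(n_class1)]
    return recs


class StubModel:
    """predict() driven by an arbitrary function of the index matrix."""

    def __init__(self, fn):
        self.fn = fn

    def predict(self, X):
        mat = X.matrix if hasattr(X, "matrix") else np.asarray(X)
        return np.asarray(self.fn(mat), dtype=float)

    def clone(self):
        return StubModel(self.fn)


def stub_bundle(decision_fn, survival_fn):
    return EFCNBundle(
        decision_model=StubModel(decision_fn),
        survival_model=StubModel(survival_fn),
        transfer_manifest={},
        training_history={},
        seeds={},
    )


class TestAssignCohorts:
    def test_fifteen_hospitals_three_cohorts_of_five(self):
        records = []
        for i in range(15):
            # hospital i has Class-0 rate (30 - i) / 100 over 100 records
            records += hosp_records(f"H{i:02d}", 30 - i, 70 + i)
        out = assign_cohorts(records, min_instances=75)
        assert [len(c) for c in out.cohorts] == [5, 5, 5]
        assert out.cohorts[0] == tuple(f"H{i:02d}" for i in range(5))
        assert out.cohorts[2] == tuple(f"H{i:02d}" for i in range(10, 15))
        assert out.cpc12_rates[0] > out.cpc12_rates[1] > out.cpc12_rates[2]

    def test_low_volume_hospitals_excluded_with_reason(self):
        records = []
        for i in range(15):
            records += hosp_records(f"H{i:02d}", 20 - i, 60 + i)
        records += hosp_records("H99", 5, 5)  # only 10 instances
        out = assign_cohorts(records, min_instances=75)
        assert "H99" in out.excluded_hospitals
        assert "min_instances" in out.excluded_hospitals["H99"]

    def test_all_below_threshold_errors(self):
        records = hosp_records("H1", 3, 3) + hosp_records("H2", 2, 4)
        with pytest.raises(ValueError, match="required"):
            assign_cohorts(records, min_instances=75)

    def test_tie_break_by_volume_then_id(self):
        records = []
        # same 50% rate everywhere; volumes distinguish, then ids
        for i, n in enumerate([60, 50, 50, 40, 40, 40]):
            records += hosp_records(f"H{i}", n, n)
        out = assign_cohorts(
            records, min_instances=10, hospitals_per_cohort=2, n_cohorts=3
        )
        assert out.cohorts[0] == ("H0", "H1")
        assert out.cohorts[1] == ("H2", "H3")
        assert out.cohorts[2] == ("H4", "H5")

    def test_excess_qualifying_hospitals_marked_excluded(self):
        records = []
        for i in range(16):
            records += hosp_records(f"H{i:02d}", 30 - i, 70 + i)
        out = assign_cohorts(records, min_instances=75)
        assert out.excluded_hospitals == {
            "H15": "qualifying but beyond cohort capacity"
        }

    def test_volume_threshold_uses_full_study_records(self):
        # rates come from the (train+val) records, the volume filter from the
        # whole registry
        train_val = []
        full = []
        for i in range(15):
            tv = hosp_records(f"H{i:02d}", 15 - i, 25 + i)
            train_val += tv
            full += tv + hosp_records(f"H{i:02d}", 20, 20)
        with pytest.raises(ValueError):
            assign_cohorts(train_val, min_instances=75)
        out = assign_cohorts(train_val, min_instances=75, volume_records=full)
        assert [len(c) for c in out.cohorts] == [5, 5, 5]


class TestCounterfactualAudit:
    @pytest.fixture(scope="class")
    def toy(self):
        schema = make_toy_schema((2, 4, 2))
        levels = lambda f, i: schema.levels(f)[i]  # noqa: E731
        rows = [  # (f0, f1, ca)
            (0, 0, 0),
            (0, 1, 0),
            (1, 0, 0),
            (0, 2, 0),
            (1, 1, 1),
            (0, 3, 1),
        ]
        records = [
            PatientRecord(
                {"f0": levels("f0", a), "f1": levels("f1", b), "f2": levels("f2", 0)},
                "HX",
                ca,
                1,
            )
            for a, b, ca in rows
        ]
        decision_fn = lambda m: np.where(m[:, 0] == 0, 0.8, 0.2)  # noqa: E731
        # survival input appends CA last: class-1 probability 0.9 without CA;
        # with CA it drops to 0.1 only when f1 is at its first level
        survival_fn = lambda m: np.where(  # noqa: E731
            m[:, -1] == 0, 0.9, np.where(m[:, 1] == 0, 0.1, 0.6)
        )
        return schema, records, stub_bundle(decision_fn, survival_fn)

    def test_hand_enumerated_counts(self, toy):
        schema, records, bundle = toy
        table = counterfactual_audit(bundle, records, schema, threshold=0.5)
        # 4 no-CA patients; f0=0 flips (3); of those only f1 level 0 improves
        assert table.n_total == 6
        assert table.n_no_initial_ca == 4
        assert table.n_flipped_to_ca == 3
        assert table.n_positive_change == 1
        assert table.n_no_change == 2
        assert table.n_negative_change == 0

    def test_negative_change_detected(self, toy):
        schema, records, _ = toy
        bundle = stub_bundle(
            lambda m: np.full(len(m), 0.9),
            lambda m: np.where(m[:, -1] == 0, 0.3, 0.7),
        )
        table = counterfactual_audit(bundle, records, schema)
        assert table.n_negative_change == table.n_flipped_to_ca == 4

    def test_never_flipping_model_yields_zero_counts(self, toy):
        schema, records, _ = toy
        bundle = stub_bundle(lambda m: np.zeros(len(m)), lambda m: np.zeros(len(m)))
        table = counterfactual_audit(bundle, records, schema)
        assert table.n_flipped_to_ca == 0
        assert table.n_positive_change == table.n_negative_change == 0

    def test_all_ca_cohort_warns_and_returns_empty(self, toy):
        schema, records, bundle = toy
        all_ca = [dataclasses.replace(r, ca_performed=1) for r in records]
        with pytest.warns(UserWarning, match="no records without"):
            table = counterfactual_audit(bundle, all_ca, schema)
        assert table.n_no_initial_ca == 0

    def test_threshold_monotonicity(self, toy):
        schema, records, _ = toy
        rng = np.random.default_rng(0)
        scores = rng.random(64)
        bundle = stub_bundle(
            lambda m: scores[: len(m)], lambda m: rng.random(len(m))
        )
        flips = [
            counterfactual_audit(bundle, records, schema, threshold=t).n_flipped_to_ca
            for t in (0.1, 0.3, 0.5, 0.7, 0.9)
        ]
        assert flips == sorted(flips, reverse=True)

    def test_accounting_identity_fuzzed(self, toy):
        schema, _, _ = toy
        rng = np.random.default_rng(42)
        for trial in range(100):
            records = make_toy_records(
                make_toy_schema((2, 4, 2)), rng.integers(2, 30), seed=trial
            )
            a, b = rng.random(2)
            bundle = stub_bundle(
                lambda m, a=a: (m[:, 1] + a) / (m[:, 1].max() + 1 + a),
                lambda m, b=b: (m.sum(axis=1) % 7 + b) / (8 + b),
            )
            t = counterfactual_audit(bundle, records, schema, threshold=rng.uniform(0.1, 0.9))
            assert t.n_flipped_to_ca == t.n_no_change + t.n_positive_change + t.n_negative_change
            assert 0 <= t.n_flipped_to_ca <= t.n_no_initial_ca <= t.n_total

    def test_leakage_guard_rejects_non_cohort_rows(self, toy):
        schema, records, bundle = toy
        registry = [dataclasses.replace(r) for r in records for _ in range(20)]
        split = split_data(registry, seed=0)
        train_rows = split.subset(registry, "train")
        with pytest.raises(ValueError, match="leakage"):
            counterfactual_audit(
                bundle, train_rows[:3], schema, split=split, registry=registry
            )
        ok_rows = split.subset(registry, "cohort_analysis")
        counterfactual_audit(bundle, ok_rows, schema, split=split, registry=registry)


class TestSummaries:
    def test_percentage_half_up_rounding(self):
        assert percentage(1, 16, 1) == 6.3  # 6.25 rounds half-up
        assert percentage(1, 3) == 33.33
        assert percentage(0, 23) == 0.0
        assert percentage(1, 0) is None

    def test_summary_recomputes_from_counts(self):
        table = CounterfactualTable("c", 100, 80, 40, 30, 8, 2, 0.5)
        s = summarize_table(table)
        assert s["predicted_to_get_ca"]["percent"] == 50.0
        assert s["positive_change_in_cpc_class"]["percent"] == 20.0
        assert s["negative_change_in_cpc_class"]["fraction"] == "2/40"

    def test_zero_denominator_renders_undefined(self):
        table = CounterfactualTable("c", 10, 5, 0, 0, 0, 0, 0.5)
        s = summarize_table(table)
        assert s["positive_change_in_cpc_class"]["percent"] is None
        assert "undefined" in s["positive_change_in_cpc_class"]["rendered"]

    def test_inconsistent_counts_rejected(self):
        with pytest.raises(ValueError):
            CounterfactualTable("c", 10, 5, 3, 1, 1, 2, 0.5)
        with pytest.raises(ValueError):
            CounterfactualTable("c", 10, 12, 3, 1, 1, 1, 0.5)


class TestRetrain:
    @pytest.fixture(scope="class")
    def small_bundle(self, toy_schema, toy_separable):
        return train_efcn_pair(
            toy_schema,
            EFCNArchitecture(conv_blocks=((8, 3),)),
            toy_separable[:300],
            toy_separable[300:],
            TrainConfig(max_epochs=4, patience=4),
            seed=1,
        )

    def test_zero_epochs_is_identity(self, small_bundle, toy_schema, toy_separable):
        tuned = retrain_on_cohort(
            small_bundle,
            toy_separable[:50],
            toy_separable[50:80],
            toy_schema,
            TrainConfig(max_epochs=0),
        )
        for k in small_bundle.decision_model.params:
            np.testing.assert_array_equal(
                tuned.decision_model.params[k], small_bundle.decision_model.params[k]
            )

    def test_original_bundle_unmodified(self, small_bundle, toy_schema, toy_separable):
        before = {k: v.copy() for k, v in small_bundle.decision_model.params.items()}
        retrain_on_cohort(
            small_bundle,
            toy_separable[:100],
            toy_separable[100:150],
            toy_schema,
            TrainConfig(max_epochs=2, patience=2),
        )
        for k in before:
            np.testing.assert_array_equal(
                small_bundle.decision_model.params[k], before[k]
            )

    def test_finetuning_adapts_toward_cohort_policy(self):
        """Two hospital groups with opposite CA propensities: loss-monitored
        fine-tuning on the permissive group raises predicted CA rates."""
        from postrosc.synthetic_cohort import generate

        cfg = flat_config(
            hospital_decision=(1.5, -1.5),
            hospital_quality=(0.0, 0.0),
            n_patients=1600,
        )
        records, _ = generate(cfg, seed=3)
        split = split_data(records, seed=1)
        arch = EFCNArchitecture(conv_blocks=((8, 3),))
        hyper = TrainConfig(max_epochs=5, patience=5, seed=0)
        bundle = train_efcn_pair(
            cfg.schema,
            arch,
            split.subset(records, "train"),
            split.subset(records, "validation"),
            hyper,
            seed=4,
        )
        permissive_train = [
            r for r in split.subset(records, "train") if r.hospital_id == "H0"
        ]
        permissive_val = [
            r for r in split.subset(records, "validation") if r.hospital_id == "H0"
        ]
        tuned = retrain_on_cohort(
            bundle,
            permissive_train,
            permissive_val,
            cfg.schema,
            TrainConfig(max_epochs=8, patience=8, monitor="loss", seed=0),
        )
        from postrosc.encoding import index_encode

        probe = index_encode(
            split.subset(records, "test"), cfg.schema, "decision"
        )
        assert (
            tuned.decision_model.predict(probe).mean()
            > bundle.decision_model.predict(probe).mean() + 0.03
        )


class TestBootstrap:
    def records(self, n_ca0, n_ca1, seed=0):
        schema = make_toy_schema((2, 4, 2))
        recs = make_toy_records(schema, n_ca0 + n_ca1, seed=seed)
        recs = [
            dataclasses.replace(r, ca_performed=int(i >= n_ca0))
            for i, r in enumerate(recs)
        ]
        return schema, recs

    def test_constant_statistic_zero_width(self):
        schema, recs = self.records(30, 5)
        bundle = stub_bundle(lambda m: np.ones(len(m)), lambda m: np.zeros(len(m)))
        est = bootstrap_ci(
            lambda r: counterfactual_audit(bundle, r, schema),
            recs,
            "flip_rate",
            replicates=200,
            seed=1,
        )
        assert est.lower == est.point == est.upper == 1.0

    def test_interval_contains_point(self):
        schema, recs = self.records(40, 10, seed=2)
        rng_scores = np.random.default_rng(5).random(512)
        bundle = stub_bundle(
            lambda m: rng_scores[: len(m)], lambda m: rng_scores[: len(m)]
        )
        est = bootstrap_ci(
            lambda r: counterfactual_audit(bundle, r, schema),
            recs,
            "flip_rate",
            replicates=200,
            seed=3,
        )
        assert est.lower <= est.point <= est.upper
        assert est.replicates == 200

    def test_too_few_replicates_rejected(self):
        schema, recs = self.records(10, 2)
        bundle = stub_bundle(lambda m: np.ones(len(m)), lambda m: np.zeros(len(m)))
        with pytest.raises(ValueError, match="100"):
            bootstrap_ci(
                lambda r: counterfactual_audit(bundle, r, schema),
                recs,
                replicates=50,
            )

    def test_degenerate_resamples_warned(self):
        schema, recs = self.records(2, 18, seed=4)
        bundle = stub_bundle(lambda m: np.ones(len(m)), lambda m: np.zeros(len(m)))
        with pytest.warns(UserWarning, match="degenerate"):
            bootstrap_ci(
                lambda r: counterfactual_audit(bundle, r, schema),
                recs,
                "flip_rate",
                replicates=200,
                seed=5,
            )
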