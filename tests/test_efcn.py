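"""EFCN construction, training, transfer semantics and reproducibility."""

import numpy as np
import pytest

from postrosc.data_model import labels
from postrosc.efcn import (
    EFCN,
    EFCNArchitecture,
    TrainConfig,
    build_efcn,
    expected_parameter_count,
    load_checkpoint,
    save_checkpoint,
    train_efcn,
    train_efcn_pair,
    transfer_embeddings,
)
from postrosc.encoding import index_encode
from postrosc.metrics import auroc

from .conftest import make_toy_records, make_toy_schema

SMALL_ARCH = EFCNArchitecture(conv_blocks=((8, 3), (8, 3)))
FAST = TrainConfig(batch_size=32, max_epochs=50, patience=50, seed=1)


class TestBuild:
    def test_same_seed_bit_identical_weights(self, schema):
        a = build_efcn(schema, SMALL_ARCH, "decision", seed=4)
        b = build_efcn(schema, SMALL_ARCH, "decision", seed=4)
        assert a.params.keys() == b.params.keys()
        for k in a.params:
            np.testing.assert_array_equal(a.params[k], b.params[k])

    @pytest.mark.parametrize("preset", [EFCNArchitecture(), SMALL_ARCH])
    @pytest.mark.parametrize("input_set", ["decision", "survival"])
    def test_parameter_count_matches_closed_form(self, schema, preset, input_set):
        net = build_efcn(schema, preset, input_set, seed=0)
        assert net.parameter_count() == expected_parameter_count(
            schema, preset, input_set
        )

    def test_survival_net_has_exactly_one_extra_embedding(self, schema):
        dec = build_efcn(schema, SMALL_ARCH, "decision", seed=0)
        sur = build_efcn(schema, SMALL_ARCH, "survival", seed=0)
        extra = set(sur.params) - set(dec.params)
        assert extra == {f"emb_{schema.ca_feature}"}

    def test_single_level_feature_rejected(self):
        with pytest.raises(ValueError, match=">=2 levels"):
            EFCN(["a", "b"], [1, 3], SMALL_ARCH, seed=0)

    def test_invalid_architecture_rejected(self):
        with pytest.raises(ValueError):
            EFCNArchitecture(conv_blocks=())
        with pytest.raises(ValueError):
            EFCNArchitecture(conv_blocks=((0, 3),))


class TestTraining:
    def test_separable_task_reaches_auroc_one(self, toy_schema, toy_separable):
        X = index_encode(toy_separable, toy_schema, "decision")
        y = labels(toy_separable, "decision")
        net = build_efcn(toy_schema, SMALL_ARCH, "decision", seed=2)
        train_efcn(net, (X, y), (X, y), FAST)
        assert auroc(net.predict(X), y) > 0.999

    def test_positive_records_outscore_negative_on_separable_task(
        self, toy_schema, toy_separable
    ):
        X = index_encode(toy_separable, toy_schema, "decision")
        y = np.asarray(labels(toy_separable, "decision"))
        net = build_efcn(toy_schema, SMALL_ARCH, "decision", seed=2)
        train_efcn(net, (X, y), (X, y), FAST)
        p = net.predict(X)
        assert p[y == 1].min() > p[y == 0].max()

    def test_single_class_training_labels_rejected(self, toy_schema):
        records = make_toy_records(toy_schema, 20, seed=0)
        X = index_encode(records, toy_schema, "decision")
        with pytest.raises(ValueError, match="single-class"):
            train_efcn(build_efcn(toy_schema, SMALL_ARCH, "decision", 0),
                       (X, [1] * 20), (X, [0, 1] * 10), FAST)

    def test_training_is_deterministic(self, toy_schema, toy_separable):
        X = index_encode(toy_separable, toy_schema, "decision")
        y = labels(toy_separable, "decision")
        runs = []
        for _ in range(2):
            net = build_efcn(toy_schema, SMALL_ARCH, "decision", seed=7)
            hist = train_efcn(
                net, (X, y), (X, y), TrainConfig(max_epochs=5, patience=5, seed=3)
            )
            runs.append((hist, net.predict(X)))
        assert runs[0][0] == runs[1][0]
        np.testing.assert_array_equal(runs[0][1], runs[1][1])


class TestPredict:
    @pytest.fixture(scope="class")
    def trained(self, toy_schema, toy_separable):
        X = index_encode(toy_separable, toy_schema, "decision")
        y = labels(toy_separable, "decision")
        net = build_efcn(toy_schema, SMALL_ARCH, "decision", seed=2)
        train_efcn(net, (X, y), (X, y), TrainConfig(max_epochs=10, patience=10))
        return net, X

    def test_duplicate_records_get_identical_probabilities(self, trained):
        net, X = trained
        doubled = np.vstack([X.matrix[:5], X.matrix[:5]])
        p = net.predict(doubled)
        np.testing.assert_array_equal(p[:5], p[5:])

    def test_probabilities_invariant_to_record_order(self, trained):
        net, X = trained
        perm = np.random.default_rng(0).permutation(len(X.matrix))
        np.testing.assert_allclose(
            net.predict(X.matrix[perm]), net.predict(X.matrix)[perm], atol=1e-12
        )

    def test_probabilities_in_open_unit_interval(self, trained):
        net, X = trained
        p = net.predict(X)
        assert (p > 0).all() and (p < 1).all()

    def test_width_mismatch_rejected(self, trained):
        net, X = trained
        with pytest.raises(ValueError, match="width"):
            net.predict(X.matrix[:, :-1])


class TestTransfer:
    @pytest.fixture(scope="class")
    def pair(self, toy_schema, toy_separable):
        split = 300
        return train_efcn_pair(
            toy_schema,
            SMALL_ARCH,
            toy_separable[:split],
            toy_separable[split:],
            TrainConfig(max_epochs=8, patience=8, seed=0),
            seed=5,
        )

    def test_shared_tables_identical_before_survival_training(
        self, toy_schema, toy_separable
    ):
        X = index_encode(toy_separable, toy_schema, "decision")
        y = labels(toy_separable, "decision")
        dec = build_efcn(toy_schema, SMALL_ARCH, "decision", seed=3)
        train_efcn(dec, (X, y), (X, y), TrainConfig(max_epochs=4, patience=4))
        sur, manifest = transfer_embeddings(dec, toy_schema, SMALL_ARCH, seed=9)
        for name in toy_schema.decision_inputs:
            np.testing.assert_array_equal(
                sur.embedding_table(name), dec.embedding_table(name)
            )
            assert manifest[name] == "transferred"
        assert manifest[toy_schema.ca_feature] == "randomly_initialized"
        # the fresh CA table differs from every decision-model table
        ca = sur.embedding_table(toy_schema.ca_feature)
        for name in toy_schema.decision_inputs:
            other = dec.embedding_table(name)
            if other.shape == ca.shape:
                assert not np.array_equal(ca, other)

    def test_transfer_all_copies_conv_stack(self, toy_schema):
        dec = build_efcn(toy_schema, SMALL_ARCH, "decision", seed=3)
        sur, _ = transfer_embeddings(
            dec, toy_schema, SMALL_ARCH, seed=9, transfer_all=True
        )
        np.testing.assert_array_equal(sur.params["conv0_W"], dec.params["conv0_W"])
        np.testing.assert_array_equal(sur.params["head_W"], dec.params["head_W"])

    def test_schema_mismatch_rejected(self, toy_schema):
        other = make_toy_schema((4, 4, 4, 4))
        dec = build_efcn(other, SMALL_ARCH, "decision", seed=0)
        with pytest.raises(ValueError, match="features do not match"):
            transfer_embeddings(dec, toy_schema, SMALL_ARCH, seed=1)

    def test_manifest_marks_only_ca_as_fresh(self, pair, toy_schema):
        fresh = [k for k, v in pair.transfer_manifest.items()
                 if v == "randomly_initialized"]
        assert fresh == [toy_schema.ca_feature]

    def test_shared_tables_move_during_survival_training(self, pair, toy_schema):
        moved = sum(
            not np.array_equal(
                pair.survival_model.embedding_table(n),
                pair.decision_model.embedding_table(n),
            )
            for n in toy_schema.decision_inputs
        )
        assert moved > 0

    def test_survival_training_does_not_mutate_decision_model(
        self, pair, toy_schema, toy_separable
    ):
        # retrain an identical decision model from scratch: the bundle's
        # stored decision weights must match it exactly (deep-copy contract)
        X = index_encode(toy_separable[:300], toy_schema, "decision")
        y = labels(toy_separable[:300], "decision")
        Xv = index_encode(toy_separable[300:], toy_schema, "decision")
        yv = labels(toy_separable[300:], "decision")
        ref = build_efcn(toy_schema, SMALL_ARCH, "decision", seed=5)
        train_efcn(ref, (X, y), (Xv, yv), TrainConfig(max_epochs=8, patience=8, seed=0))
        for k in ref.params:
            np.testing.assert_array_equal(ref.params[k], pair.decision_model.params[k])


def test_checkpoint_round_trip(tmp_path, toy_schema):
    net = build_efcn(toy_schema, SMALL_ARCH, "survival", seed=12)
    path = str(tmp_path / "ckpt")
    save_checkpoint(net, path)
    back = load_checkpoint(path)
    assert back.features == net.features
    for k in net.params:
        np.testing.assert_array_equal(back.params[k], net.params[k])
    X = np.zeros((3, len(net.features)), dtype=int)
    np.testing.assert_array_equal(back.predict(X), net.predict(X))
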