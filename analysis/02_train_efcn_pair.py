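#!/usr/bin/env python
"""Train the sequential EFCN pair with embedding transfer.

Reads the registry written by 01_simulate_registry.py, trains the coronary
angiography decision network on the training split with early stopping on
the validation split, transfers its embedding tables into the survival
(CPC-class) network — only the CA embedding starts fresh — and trains that
in turn.  Checkpoints, the transfer manifest and training history land in
results/analysis/.

Prints validation/test AUROCs for both tasks next to the generator's
Bayes-optimal ceiling.
"""

import json
import os
import sys

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

import pandas as pd

from postrosc.data_model import DataSplit, FeatureSchema, labels, read_registry
from postrosc.efcn import EFCNArchitecture, TrainConfig, save_checkpoint, train_efcn_pair
from postrosc.encoding import index_encode
from postrosc.metrics import auroc
from postrosc.synthetic_cohort import bayes_auroc

OUT = os.path.join(os.path.dirname(__file__), "..", "results", "analysis")
SEED = 1


def main() -> None:
    schema = FeatureSchema.from_json(os.path.join(OUT, "schema.json"))
    records = read_registry(os.path.join(OUT, "registry.csv"), schema)
    split = DataSplit.from_json(os.path.join(OUT, "split.json"))
    sidecar = pd.read_csv(os.path.join(OUT, "sidecar.csv"))

    bundle = train_efcn_pair(
        schema,
        EFCNArchitecture.compact(),
        split.subset(records, "train"),
        split.subset(records, "validation"),
        TrainConfig(max_epochs=60, patience=10, seed=SEED),
        seed=SEED,
    )
    save_checkpoint(bundle.decision_model, os.path.join(OUT, "efcn_decision"))
    save_checkpoint(bundle.survival_model, os.path.join(OUT, "efcn_survival"))
    with open(os.path.join(OUT, "transfer_manifest.json"), "w") as fh:
        json.dump(bundle.transfer_manifest, fh, indent=1)
    with open(os.path.join(OUT, "training_history.json"), "w") as fh:
        json.dump(bundle.training_history, fh)

    test_idx = split.indices("test")
    test = [records[i] for i in test_idx]
    for task, net, input_set, kind in (
        ("decision", bundle.decision_model, "decision", "decision"),
        ("survival", bundle.survival_model, "survival", "outcome"),
    ):
        X = index_encode(test, schema, input_set)
        y = labels(test, kind)
        ceiling = bayes_auroc(
            sidecar.iloc[test_idx], "decision" if task == "decision" else "outcome"
        )
        epochs = len(bundle.training_history[task])
        print(
            f"{task}: test AUROC {auroc(net.predict(X), y):.4f} "
            f"(Bayes ceiling {ceiling:.4f}, {epochs} epochs)"
        )
    fresh = [k for k, v in bundle.transfer_manifest.items()
             if v == "randomly_initialized"]
    print(f"transferred embeddings: {len(bundle.transfer_manifest) - len(fresh)}; "
          f"freshly initialized: {fresh}")


if __name__ == "__main__":
    main()
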