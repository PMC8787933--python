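#!/usr/bin/env python
"""Compare the EFCN pair against nine grid-searched classical families.

Reads the registry, split and EFCN checkpoints produced by the previous
scripts, grid-searches every classical family on one-hot inputs (selection
by validation AUROC), evaluates each family's best model on the test split,
and writes the leaderboard to results/analysis/leaderboard.csv.
"""

import os
import sys
import warnings

sys.path.insert(0, os.path.join(os.path.dirname(__file__), "..", "src"))

from postrosc.baselines import default_grids, run_leaderboard
from postrosc.data_model import DataSplit, FeatureSchema, read_registry
from postrosc.efcn import EFCNBundle, load_checkpoint

OUT = os.path.join(os.path.dirname(__file__), "..", "results", "analysis")
SEED = 1


def main() -> None:
    warnings.filterwarnings("ignore")
    schema = FeatureSchema.from_json(os.path.join(OUT, "schema.json"))
    records = read_registry(os.path.join(OUT, "registry.csv"), schema)
    split = DataSplit.from_json(os.path.join(OUT, "split.json"))
    bundle = EFCNBundle(
        decision_model=load_checkpoint(os.path.join(OUT, "efcn_decision")),
        survival_model=load_checkpoint(os.path.join(OUT, "efcn_survival")),
        transfer_manifest={},
        training_history={},
        seeds={},
    )
    board = run_leaderboard(
        records, split, schema, default_grids(seed=SEED), efcn_bundle=bundle
    )
    board.to_frame().to_csv(os.path.join(OUT, "leaderboard.csv"), index=False)
    print(board.render())


if __name__ == "__main__":
    main()
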