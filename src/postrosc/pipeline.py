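"""End-to-end orchestration: generate -> split -> encode -> train ->
leaderboard -> cohort counterfactual audit, with a manifest for
reproducibility.

One global seed fans out to per-stage seeds through
``numpy.random.SeedSequence([seed, stage_index])`` so any stage can be
reproduced in isolation.  All artifacts are plain text (CSV/JSON) except the
optional network checkpoints.  Stages run in the protocol's order: the
decision model is always trained before the survival model, and the cohort
audit only ever sees the held-out cohort-analysis split.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
import time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

import postrosc
from postrosc.baselines import LeaderBoard, ModelGrid, default_grids, run_leaderboard
from postrosc.cohort import (
    CounterfactualTable,
    assign_cohorts,
    bootstrap_ci,
    counterfactual_audit,
    retrain_on_cohort,
    summarize_table,
)
from postrosc.data_model import DataSplit, labels, split_data, write_registry
from postrosc.efcn import EFCNArchitecture, TrainConfig, train_efcn_pair
from postrosc.synthetic_cohort import bayes_auroc, default_config, generate

STAGES = (
    "generate",
    "split",
    "train_efcn",
    "leaderboard",
    "assign_cohorts",
    "retrain_cohort1",
    "audit",
)


def stage_seed(global_seed: int, stage_index: int) -> int:
    """Documented fan-out: SeedSequence([seed, stage]) -> int below 2^31."""
    return int(
        np.random.SeedSequence([global_seed, stage_index]).generate_state(1)[0]
        % 2**31
    )


@dataclass
class PipelineConfig:
    n_patients: int = 2398
    seed: int = 0
    proportions: tuple[float, float, float, float] = (0.40, 0.10, 0.25, 0.25)
    arch_preset: str = "compact"  # "compact" or "full"
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 60
    patience: int = 10
    finetune_epochs: int = 30
    families: Optional[tuple[str, ...]] = None  # None = all nine
    min_instances: int = 75
    hospitals_per_cohort: int = 5
    n_cohorts: int = 3
    threshold: float = 0.5
    bootstrap_replicates: int = 1000
    save_checkpoints: bool = False

    def architecture(self) -> EFCNArchitecture:
        if self.arch_preset == "compact":
            return EFCNArchitecture.compact()
        if self.arch_preset == "full":
            return EFCNArchitecture()
        raise ValueError(f"unknown arch preset {self.arch_preset!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["proportions"] = list(self.proportions)
        d["families"] = list(self.families) if self.families else None
        return d

    @classmethod
    def from_json(cls, path: str) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        if "proportions" in payload:
            payload["proportions"] = tuple(payload["proportions"])
        if payload.get("families"):
            payload["families"] = tuple(payload["families"])
        return cls(**payload)


@dataclass
class RunManifest:
    config_hash: str
    global_seed: int
    stage_seeds: dict[str, int]
    split_sizes: dict[str, int]
    artifacts: dict[str, str]
    version: str
    wall_times: dict[str, float]

    def to_json(self, path: str) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=1)


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig, out_dir: str) -> RunManifest:
    """Execute every stage and write all artifacts under ``out_dir``."""
    os.makedirs(out_dir, exist_ok=True)
    seeds = {name: stage_seed(config.seed, i) for i, name in enumerate(STAGES)}
    artifacts: dict[str, str] = {}
    times: dict[str, float] = {}

    def path(name: str) -> str:
        return os.path.join(out_dir, name)

    t0 = time.time()
    gen_config = default_config(n_patients=config.n_patients, seed=seeds["generate"])
    registry, sidecar = generate(gen_config)
    schema = gen_config.schema
    write_registry(registry, schema, path("registry.csv"))
    sidecar.to_csv(path("sidecar.csv"), index=False)
    schema.to_json(path("schema.json"))
    artifacts["registry"] = path("registry.csv")
    artifacts["sidecar"] = path("sidecar.csv")
    artifacts["schema"] = path("schema.json")
    times["generate"] = time.time() - t0

    t0 = time.time()
    split = split_data(registry, config.proportions, seed=seeds["split"])
    split.to_json(path("split.json"))
    artifacts["split"] = path("split.json")
    times["split"] = time.time() - t0

    t0 = time.time()
    hyper = TrainConfig(
        learning_rate=config.learning_rate,
        batch_size=config.batch_size,
        max_epochs=config.max_epochs,
        patience=config.patience,
        seed=seeds["train_efcn"],
    )
    bundle = train_efcn_pair(
        schema,
        config.architecture(),
        split.subset(registry, "train"),
        split.subset(registry, "validation"),
        hyper,
        seed=seeds["train_efcn"],
    )
    if config.save_checkpoints:
        from postrosc.efcn import save_checkpoint

        save_checkpoint(bundle.decision_model, path("efcn_decision"))
        save_checkpoint(bundle.survival_model, path("efcn_survival"))
        artifacts["efcn_decision"] = path("efcn_decision.npz")
        artifacts["efcn_survival"] = path("efcn_survival.npz")
    with open(path("training_history.json"), "w", encoding="utf-8") as fh:
        json.dump(bundle.training_history, fh)
    artifacts["training_history"] = path("training_history.json")
    times["train_efcn"] = time.time() - t0

    t0 = time.time()
    grids = default_grids(seed=seeds["leaderboard"])
    if config.families is not None:
        grids = [g for g in grids if g.family in config.families]
    # the leaderboard's confusion-matrix threshold is the conventional 0.5;
    # config.threshold governs the audit's decision rule only
    board = run_leaderboard(
        registry, split, schema, grids, efcn_bundle=bundle, threshold=0.5
    )
    board.to_frame().to_csv(path("leaderboard.csv"), index=False)
    artifacts["leaderboard"] = path("leaderboard.csv")
    times["leaderboard"] = time.time() - t0

    t0 = time.time()
    train_val = split.subset(registry, "train") + split.subset(registry, "validation")
    assignment = assign_cohorts(
        train_val,
        min_instances=config.min_instances,
        hospitals_per_cohort=config.hospitals_per_cohort,
        n_cohorts=config.n_cohorts,
        volume_records=registry,
    )
    with open(path("cohorts.json"), "w", encoding="utf-8") as fh:
        json.dump(
            {
                "cohorts": [list(c) for c in assignment.cohorts],
                "cpc12_rates": list(assignment.cpc12_rates),
                "excluded": assignment.excluded_hospitals,
            },
            fh,
            indent=1,
        )
    artifacts["cohorts"] = path("cohorts.json")
    times["assign_cohorts"] = time.time() - t0

    t0 = time.time()
    cohort1 = set(assignment.cohorts[0])
    # fine-tuning is monitored on validation loss: the audit thresholds raw
    # probabilities, so cohort-specific calibration matters, and AUROC is
    # blind to the intercept shift that cohort adaptation mostly is
    ft_hyper = dataclasses.replace(
        hyper,
        max_epochs=config.finetune_epochs,
        seed=seeds["retrain_cohort1"],
        monitor="loss",
    )
    cohort1_bundle = retrain_on_cohort(
        bundle,
        [r for r in split.subset(registry, "train") if r.hospital_id in cohort1],
        [r for r in split.subset(registry, "validation") if r.hospital_id in cohort1],
        schema,
        ft_hyper,
    )
    times["retrain_cohort1"] = time.time() - t0

    t0 = time.time()
    analysis_records = split.subset(registry, "cohort_analysis")
    audit_rows = []
    ci_rows = {}
    for k in range(1, config.n_cohorts):
        members = set(assignment.cohorts[k])
        targets = [r for r in analysis_records if r.hospital_id in members]
        label = f"cohort{k + 1}"
        table = counterfactual_audit(
            cohort1_bundle,
            targets,
            schema,
            threshold=config.threshold,
            cohort_label=label,
            split=split,
            registry=registry,
        )
        summary = summarize_table(table)
        audit_rows.append({**table.to_dict(), "summary": summary})
        if config.bootstrap_replicates and table.n_flipped_to_ca > 0:
            audit_fn = lambda recs: counterfactual_audit(  # noqa: E731
                cohort1_bundle, recs, schema, threshold=config.threshold
            )
            ci_rows[label] = {}
            for stat in ("flip_rate", "positive_change_rate"):
                est = bootstrap_ci(
                    audit_fn,
                    targets,
                    statistic=stat,
                    replicates=config.bootstrap_replicates,
                    seed=seeds["audit"],
                )
                ci_rows[label][stat] = {
                    "point": est.point,
                    "lower": est.lower,
                    "upper": est.upper,
                    "replicates": est.replicates,
                }
    with open(path("audit.json"), "w", encoding="utf-8") as fh:
        json.dump({"tables": audit_rows, "bootstrap": ci_rows}, fh, indent=1)
    artifacts["audit"] = path("audit.json")
    # flat CSV of the audit counts for determinism checks / downstream use
    import pandas as pd

    pd.DataFrame([row | {"summary": json.dumps(row["summary"])} for row in audit_rows]).to_csv(
        path("audit.csv"), index=False
    )
    artifacts["audit_csv"] = path("audit.csv")
    times["audit"] = time.time() - t0

    manifest = RunManifest(
        config_hash=_config_hash(config),
        global_seed=config.seed,
        stage_seeds=seeds,
        split_sizes=split.sizes(),
        artifacts=artifacts,
        version=postrosc.__version__,
        wall_times=times,
    )
    manifest.to_json(path("manifest.json"))
    with open(path("config.json"), "w", encoding="utf-8") as fh:
        json.dump(config.to_dict(), fh, indent=1)
    report = make_report(out_dir)
    with open(path("report.txt"), "w", encoding="utf-8") as fh:
        fh.write(report)
    return manifest


def make_report(out_dir: str) -> str:
    """Human-readable summary assembled only from artifact files."""
    import pandas as pd

    required = ["manifest.json", "leaderboard.csv", "audit.json", "cohorts.json"]
    missing = [f for f in required if not os.path.exists(os.path.join(out_dir, f))]
    if missing:
        raise FileNotFoundError(f"missing artifacts in {out_dir}: {missing}")
    with open(os.path.join(out_dir, "manifest.json"), encoding="utf-8") as fh:
        manifest = json.load(fh)
    with open(os.path.join(out_dir, "cohorts.json"), encoding="utf-8") as fh:
        cohorts = json.load(fh)
    with open(os.path.join(out_dir, "audit.json"), encoding="utf-8") as fh:
        audit = json.load(fh)
    board = pd.read_csv(os.path.join(out_dir, "leaderboard.csv"))

    lines = [
        "Post-ROSC decision/outcome modeling run",
        f"  config hash {manifest['config_hash']}, seed {manifest['global_seed']}",
        f"  split sizes: {manifest['split_sizes']}",
        "",
        "Model leaderboard (validation AUROC, best first per task):",
    ]
    for task in ("decision", "survival"):
        sub = board[board.task == task].sort_values(
            "validation_auroc", ascending=False
        )
        lines.append(f"  task: {task}")
        for r in sub.itertuples(index=False):
            lines.append(
                f"    {r.family:<20} val {r.validation_auroc:.4f}"
                f"  test {r.test_auroc:.4f}"
            )
    lines += ["", "Hospital cohorts (best to worst CPC1/2 rate, train+validation):"]
    for i, (members, rate) in enumerate(
        zip(cohorts["cohorts"], cohorts["cpc12_rates"])
    ):
        lines.append(f"  Cohort {i + 1}: rate {100 * rate:.1f}%  hospitals {members}")
    lines += ["", "Counterfactual audit (best-cohort models on worse cohorts):"]
    for row in audit["tables"]:
        lines.append(f"  {row['cohort']} (N = {row['n_total']}):")
        for name, cell in row["summary"].items():
            lines.append(f"    {name.replace('_', ' ')}: {cell['rendered']}")
        cis = audit["bootstrap"].get(row["cohort"])
        if cis:
            for stat, est in cis.items():
                lines.append(
                    f"    {stat} 95% CI: {100 * est['point']:.1f}% "
                    f"({100 * est['lower']:.1f}-{100 * est['upper']:.1f}), "
                    f"{est['replicates']} replicates"
                )
    return "\n".join(lines) + "\n"
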