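"""Classical-model comparison harness.

Nine model families — lightgbm and xgboost gradient boosting, decision tree,
random forest, scikit-learn gradient boosting, k-nearest neighbor, logistic
regression, support vector machine, and a dense neural network — each grid
searched over a modest declared parameter grid and selected by validation
AUROC, then evaluated on the untouched test split.  All classical models
consume one-hot inputs; only the EFCN consumes index/embedding inputs.

The default grids are deliberately small, documented stand-ins (the tuned
grids behind the original analysis are not public); user grids are accepted
per family.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from postrosc.metrics import MetricReport, auroc, compute_metrics

FAMILIES = (
    "lightgbm",
    "xgboost",
    "decision_tree",
    "random_forest",
    "gradient_boosting",
    "knn",
    "logistic_regression",
    "svm",
    "dense_nn",
)


@dataclass(frozen=True)
class ModelGrid:
    family: str
    parameter_grid: dict[str, tuple]
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if not self.parameter_grid or any(
            len(v) == 0 for v in self.parameter_grid.values()
        ):
            raise ValueError("parameter grid must be non-empty")

    def points(self) -> list[dict]:
        """Grid points in declaration order (first-in-grid tie-break order)."""
        names = list(self.parameter_grid)
        return [
            dict(zip(names, combo))
            for combo in itertools.product(*(self.parameter_grid[n] for n in names))
        ]


def default_grids(seed: int = 0) -> list[ModelGrid]:
    return [
        ModelGrid("lightgbm", {"num_leaves": (15, 31), "n_estimators": (100, 300)}, seed),
        ModelGrid("xgboost", {"max_depth": (3, 5), "n_estimators": (100, 300)}, seed),
        ModelGrid("decision_tree", {"max_depth": (3, 5, 7, None)}, seed),
        ModelGrid("random_forest", {"max_depth": (5, None), "n_estimators": (100, 300)}, seed),
        ModelGrid("gradient_boosting", {"max_depth": (2, 3), "n_estimators": (100, 300)}, seed),
        ModelGrid("knn", {"n_neighbors": (5, 11, 21)}, seed),
        ModelGrid("logistic_regression", {"C": (0.01, 0.1, 1.0, 10.0)}, seed),
        ModelGrid("svm", {"C": (0.1, 1.0, 10.0)}, seed),
        ModelGrid("dense_nn", {"hidden_layer_sizes": ((32,), (64, 32)), "alpha": (1e-4, 1e-2)}, seed),
    ]


def _make_model(family: str, params: dict, seed: int):
    if family == "lightgbm":
        import lightgbm as lgb

        return lgb.LGBMClassifier(
            random_state=seed, deterministic=True, n_jobs=1, verbose=-1, **params
        )
    if family == "xgboost":
        import xgboost as xgb

        return xgb.XGBClassifier(
            random_state=seed, n_jobs=1, eval_metric="logloss", **params
        )
    from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.neural_network import MLPClassifier
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier

    if family == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **params)
    if family == "random_forest":
        return RandomForestClassifier(random_state=seed, n_jobs=1, **params)
    if family == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed, **params)
    if family == "knn":
        return KNeighborsClassifier(n_jobs=1, **params)
    if family == "logistic_regression":
        return LogisticRegression(random_state=seed, max_iter=2000, **params)
    if family == "svm":
        return SVC(random_state=seed, probability=True, **params)
    if family == "dense_nn":
        return MLPClassifier(random_state=seed, max_iter=500, **params)
    raise ValueError(family)


@dataclass
class LeaderBoardRow:
    family: str
    task: str
    best_params: dict
    validation_auroc: float
    test_metrics: Optional[MetricReport] = None


def grid_search(
    grid: ModelGrid,
    train: tuple[np.ndarray, Sequence[int]],
    validation: tuple[np.ndarray, Sequence[int]],
    task: str,
):
    """Exhaustive search, argmax validation AUROC, first-in-grid tie-break.

    Returns the refitted best model and its leaderboard row.
    """
    Xtr, ytr = np.asarray(train[0], dtype=float), np.asarray(train[1])
    Xva, yva = np.asarray(validation[0], dtype=float), np.asarray(validation[1])
    best_auc, best_params, best_model = -np.inf, None, None
    for params in grid.points():
        model = _make_model(grid.family, params, grid.seed)
        model.fit(Xtr, ytr)
        auc = auroc(model.predict_proba(Xva)[:, 1], yva)
        if auc > best_auc:  # strict: ties keep the earlier grid point
            best_auc, best_params, best_model = auc, params, model
    row = LeaderBoardRow(
        family=grid.family,
        task=task,
        best_params=best_params,
        validation_auroc=float(best_auc),
    )
    return best_model, row


@dataclass
class LeaderBoard:
    rows: list[LeaderBoardRow]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "family": [r.family for r in self.rows],
                "task": [r.task for r in self.rows],
                "validation_auroc": [r.validation_auroc for r in self.rows],
                "test_auroc": [
                    r.test_metrics.auroc if r.test_metrics else np.nan
                    for r in self.rows
                ],
                "best_params": [repr(r.best_params) for r in self.rows],
            }
        )

    def render(self) -> str:
        """Validation/test AUROC per family and task, best family first."""
        frame = self.to_frame().sort_values(
            ["task", "validation_auroc"], ascending=[True, False]
        )
        lines = ["family                task      val AUROC  test AUROC"]
        for r in frame.itertuples(index=False):
            test = "" if np.isnan(r.test_auroc) else f"{r.test_auroc:.4f}"
            lines.append(
                f"{r.family:<21} {r.task:<9} {r.validation_auroc:.4f}     {test}"
            )
        return "\n".join(lines)


def run_leaderboard(
    registry,
    split,
    schema,
    grids: Optional[list[ModelGrid]] = None,
    efcn_bundle=None,
    threshold: float = 0.5,
) -> LeaderBoard:
    """Both tasks, every family plus the EFCN, on identical splits.

    Classical models see one-hot matrices; the EFCN rows re-use the provided
    trained bundle (trained on the same split by the caller).  Each family's
    best-by-validation model is evaluated once on the test split.
    """
    from postrosc.data_model import labels
    from postrosc.encoding import index_encode, one_hot_encode

    grids = default_grids() if grids is None else grids
    train = split.subset(registry, "train")
    validation = split.subset(registry, "validation")
    test = split.subset(registry, "test")
    rows: list[LeaderBoardRow] = []
    for task, input_set, label_kind in (
        ("decision", "decision", "decision"),
        ("survival", "survival", "outcome"),
    ):
        Xtr = one_hot_encode(train, schema, input_set).matrix
        Xva = one_hot_encode(validation, schema, input_set).matrix
        Xte = one_hot_encode(test, schema, input_set).matrix
        ytr = labels(train, label_kind)
        yva = labels(validation, label_kind)
        yte = labels(test, label_kind)
        for grid in grids:
            model, row = grid_search(grid, (Xtr, ytr), (Xva, yva), task)
            row.test_metrics = compute_metrics(
                model.predict_proba(Xte.astype(float))[:, 1], yte, threshold
            )
            rows.append(row)
        if efcn_bundle is not None:
            net = (
                efcn_bundle.decision_model
                if task == "decision"
                else efcn_bundle.survival_model
            )
            Xva_i = index_encode(validation, schema, input_set)
            Xte_i = index_encode(test, schema, input_set)
            rows.append(
                LeaderBoardRow(
                    family="efcn",
                    task=task,
                    best_params={},
                    validation_auroc=auroc(net.predict(Xva_i), yva),
                    test_metrics=compute_metrics(net.predict(Xte_i), yte, threshold),
                )
            )
    return LeaderBoard(rows=rows)
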