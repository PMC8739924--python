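"""Lesion-extent classification from pulse features.

Three dataset compositions are evaluated, each built on the demographic
baseline (age, sex, BMI):

* ``dataset1`` — baseline + the nine time-domain features (12 columns),
* ``dataset2`` — baseline + the five multiscale-entropy features (8 columns),
* ``dataset3`` — the union (17 columns),

with labels 1 (< 50% stenosis control), 2 (1-2 lesions), 3 (>= 3 lesions).
Three classifiers (k-nearest neighbours, decision tree, random forest) are
scored by stratified k-fold cross-validation: out-of-fold predictions are
pooled, per-class precision is TP/(TP+FP) on the pooled predictions, and
the average (macro) precision is the unweighted mean of the three per-class
precisions. Features are median-imputed within training folds; KNN
additionally standardises features within training folds; the decision
tree is cost-complexity pruned, its pruning strength selected by an inner
cross-validation within each training fold. All randomness derives from
the ``seed`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.metrics import make_scorer, precision_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold, cross_val_predict
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .exceptions import ParameterError
from .fiducial import TD_FEATURE_NAMES

__all__ = [
    "FeatureDataset",
    "EvaluationRow",
    "ClassificationReport",
    "BASELINE_COLUMNS",
    "MSE_COLUMNS",
    "ALGORITHMS",
    "DATASET_NAMES",
    "build_datasets",
    "evaluate",
    "compare_models",
]

BASELINE_COLUMNS = ("age", "sex", "bmi")
MSE_COLUMNS = ("mse1", "mse2", "mse3", "mse4", "mse5")
DATASET_COLUMNS = {
    "dataset1": BASELINE_COLUMNS + TD_FEATURE_NAMES,
    "dataset2": BASELINE_COLUMNS + MSE_COLUMNS,
    "dataset3": BASELINE_COLUMNS + TD_FEATURE_NAMES + MSE_COLUMNS,
}
DATASET_NAMES = tuple(DATASET_COLUMNS)
ALGORITHMS = ("knn", "dt", "rf")
CLASS_LABELS = (1, 2, 3)


@dataclass(frozen=True)
class FeatureDataset:
    """A named subjects x features matrix with lesion-group labels."""

    name: str
    X: np.ndarray
    y: np.ndarray
    feature_names: tuple[str, ...]
    subject_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=float)
        y = np.asarray(self.y, dtype=int)
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)
        if X.ndim != 2 or X.shape[0] != y.size:
            raise ParameterError("X must be 2-D with one row per label")
        if X.shape[1] != len(self.feature_names):
            raise ParameterError("feature_names must match the number of columns")


@dataclass(frozen=True)
class EvaluationRow:
    algorithm: str
    dataset: str
    precisions: dict  # class label -> precision in %
    average_precision: float  # unweighted mean of per-class precisions, %
    folds: int
    seed: int


@dataclass(frozen=True)
class ClassificationReport:
    """All algorithm x dataset evaluations plus a ranking summary."""

    rows: tuple[EvaluationRow, ...]
    folds: int
    seed: int

    def row(self, algorithm: str, dataset: str) -> EvaluationRow:
        for r in self.rows:
            if r.algorithm == algorithm and r.dataset == dataset:
                return r
        raise KeyError((algorithm, dataset))

    def ranking(self) -> dict:
        """Best algorithm per dataset and best dataset per algorithm."""
        best_alg = {
            d: max((r for r in self.rows if r.dataset == d),
                   key=lambda r: r.average_precision).algorithm
            for d in DATASET_NAMES
        }
        best_ds = {
            a: max((r for r in self.rows if r.algorithm == a),
                   key=lambda r: r.average_precision).dataset
            for a in ALGORITHMS
        }
        return {"best_algorithm_per_dataset": best_alg,
                "best_dataset_per_algorithm": best_ds}

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {"algorithm": r.algorithm, "dataset": r.dataset,
                 **{f"precision_group{c}": r.precisions[c] for c in CLASS_LABELS},
                 "average_precision": r.average_precision,
                 "folds": r.folds, "seed": r.seed}
                for r in self.rows
            ]
        )


def _encode_sex(col) -> np.ndarray:
    values = []
    mapping = {"m": 1, "male": 1, "1": 1, "f": 0, "female": 0, "0": 0}
    for v in col:
        if isinstance(v, str):
            key = v.strip().lower()
            if key not in mapping:
                raise ParameterError(f"cannot encode sex value {v!r}")
            values.append(mapping[key])
        else:
            values.append(int(v))
    return np.asarray(values, dtype=float)


def build_datasets(cohort) -> dict[str, FeatureDataset]:
    """Assemble the three dataset compositions from a cohort feature table.

    The cohort is sorted by ``subject_id`` (when present) so that fold
    assignment is invariant to row order; column order is fixed by the
    canonical composition lists.
    """
    import pandas as pd

    df = pd.DataFrame(cohort)
    if "group" not in df.columns:
        raise ParameterError("cohort table lacks a 'group' label column")
    if df["group"].isna().any():
        raise ParameterError("cohort table has missing group labels")
    if "subject_id" in df.columns:
        df = df.sort_values("subject_id", kind="mergesort").reset_index(drop=True)
        ids = tuple(df["subject_id"].astype(str))
    else:
        ids = ()
    y = df["group"].to_numpy(dtype=int)
    datasets = {}
    for name, columns in DATASET_COLUMNS.items():
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise ParameterError(f"{name}: cohort table lacks column(s) {missing}")
        X = np.column_stack(
            [
                _encode_sex(df[c]) if c == "sex" else df[c].to_numpy(dtype=float)
                for c in columns
            ]
        )
        datasets[name] = FeatureDataset(name, X, y, tuple(columns), ids)
    return datasets


#: cost-complexity pruning strengths searched by the decision tree's
#: internal cross-validation (0 = no pruning)
DT_CCP_ALPHAS = (0.0, 0.001, 0.002, 0.005, 0.01, 0.02)


def _make_model(algorithm: str, seed: int, *, knn_k: int, rf_trees: int,
                dt_inner_splits: int = 5):
    imputer = ("impute", SimpleImputer(strategy="median"))
    if algorithm == "knn":
        return Pipeline([imputer, ("scale", StandardScaler()),
                         ("clf", KNeighborsClassifier(n_neighbors=knn_k))])
    if algorithm == "dt":
        # the tree is grown with Gini splits and then cost-complexity
        # pruned, the pruning strength chosen by an inner stratified CV on
        # macro precision (the metric the evaluation reports); tiny inputs
        # fall back to an unpruned tree
        tree = DecisionTreeClassifier(criterion="gini", random_state=seed)
        if dt_inner_splits >= 2:
            inner_cv = StratifiedKFold(n_splits=dt_inner_splits, shuffle=True,
                                       random_state=seed)
            scorer = make_scorer(precision_score, average="macro", zero_division=0)
            tree = GridSearchCV(
                tree, {"ccp_alpha": list(DT_CCP_ALPHAS)},
                cv=inner_cv, scoring=scorer, n_jobs=1,
            )
        return Pipeline([imputer, ("clf", tree)])
    if algorithm == "rf":
        return Pipeline([imputer,
                         ("clf", RandomForestClassifier(n_estimators=rf_trees,
                                                        random_state=seed))])
    raise ParameterError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")


def evaluate(
    dataset: FeatureDataset,
    algorithm: str,
    *,
    folds: int = 10,
    seed: int = 0,
    knn_k: int = 5,
    rf_trees: int = 500,
) -> EvaluationRow:
    """Cross-validated per-class and macro precision for one model."""
    classes, counts = np.unique(dataset.y, return_counts=True)
    if classes.size < 2:
        raise ParameterError("need at least 2 classes present")
    if counts.min() < folds:
        raise ParameterError(
            f"smallest class has {counts.min()} subjects < folds={folds}"
        )
    min_train = int(counts.min() * (folds - 1) // folds)
    model = _make_model(algorithm, seed, knn_k=knn_k, rf_trees=rf_trees,
                        dt_inner_splits=min(5, min_train))
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = cross_val_predict(model, dataset.X, dataset.y, cv=cv)
    per_class = precision_score(
        dataset.y, pred, labels=list(classes), average=None, zero_division=0
    ) * 100.0
    precisions = {int(c): float(p) for c, p in zip(classes, per_class)}
    return EvaluationRow(
        algorithm=algorithm,
        dataset=dataset.name,
        precisions=precisions,
        average_precision=float(np.mean(per_class)),
        folds=folds,
        seed=seed,
    )


def compare_models(
    cohort,
    *,
    folds: int = 10,
    seed: int = 0,
    knn_k: int = 5,
    rf_trees: int = 500,
) -> ClassificationReport:
    """Evaluate every algorithm on every dataset composition (9 rows)."""
    datasets = build_datasets(cohort)
    rows = tuple(
        evaluate(datasets[d], a, folds=folds, seed=seed, knn_k=knn_k, rf_trees=rf_trees)
        for a in ALGORITHMS
        for d in DATASET_NAMES
    )
    return ClassificationReport(rows=rows, folds=folds, seed=seed)
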