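"""Random-forest discrimination of cell classes.

Evaluation is repeated stratified k-fold cross-validation with per-fold
median imputation of masked features (plus missing indicators), so no
information leaks from held-out cells into the imputer.  Sensitivity is
the recall of the positive class (CTC candidates by default), specificity
the recall of the other class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.inspection import permutation_importance as _sk_permutation_importance
from sklearn.model_selection import RepeatedStratifiedKFold, train_test_split
from sklearn.pipeline import Pipeline

from .features import FeatureMatrix

__all__ = [
    "RFConfig",
    "ClassificationReport",
    "train_and_evaluate",
    "evaluate_counts",
    "permutation_importance",
    "progressive_input",
]


@dataclass(frozen=True)
class RFConfig:
    """Random-forest and cross-validation settings.

    Defaults: 500 Gini trees with sqrt-features per split, stratified
    5-fold cross-validation repeated 10 times, no class weighting,
    positive class ``CTC_candidate``.
    """

    n_trees: int = 500
    split_criterion: str = "gini"
    max_features: str | float = "sqrt"
    cv_folds: int = 5
    cv_repeats: int = 10
    positive_class: str = "CTC_candidate"
    seed: int = 0
    class_weighting: str | None = None  # None or "balanced"
    n_permutations: int = 10
    holdout_fraction: float = 0.25

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


@dataclass
class ClassificationReport:
    """Cross-validated metrics plus summed confusion counts."""

    accuracy: float
    sensitivity: float
    specificity: float
    tp: int
    fp: int
    tn: int
    fn: int
    per_fold: pd.DataFrame
    positive_class: str
    importances: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
            "positive_class": self.positive_class,
        }
        if self.importances is not None:
            d["importances"] = self.importances.to_dict(orient="records")
        return d


def _make_pipeline(config: RFConfig) -> Pipeline:
    return Pipeline(
        [
            ("impute", SimpleImputer(strategy="median", add_indicator=True)),
            (
                "rf",
                RandomForestClassifier(
                    n_estimators=config.n_trees,
                    criterion=config.split_criterion,
                    max_features=config.max_features,
                    class_weight=config.class_weighting,
                    random_state=config.seed % (2**31),
                    n_jobs=1,
                ),
            ),
        ]
    )


def evaluate_counts(tp: int, fp: int, tn: int, fn: int) -> tuple[float, float, float]:
    """Accuracy, sensitivity and specificity from confusion counts.

    Zero-denominator metrics come back as NaN rather than a silent value.
    """
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("confusion counts must be >= 0")
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("confusion counts must not all be zero")
    accuracy = (tp + tn) / total
    sensitivity = tp / (tp + fn) if tp + fn > 0 else float("nan")
    specificity = tn / (tn + fp) if tn + fp > 0 else float("nan")
    return accuracy, sensitivity, specificity


def _cv_splits(matrix: FeatureMatrix, config: RFConfig) -> list[tuple[np.ndarray, np.ndarray]]:
    cv = RepeatedStratifiedKFold(
        n_splits=config.cv_folds,
        n_repeats=config.cv_repeats,
        random_state=config.seed % (2**31),
    )
    return list(cv.split(matrix.X.values, matrix.y.values))


def train_and_evaluate(
    matrix: FeatureMatrix,
    config: RFConfig | None = None,
    splits: list[tuple[np.ndarray, np.ndarray]] | None = None,
    feature_subset: list[str] | None = None,
) -> ClassificationReport:
    """Repeated stratified cross-validation of the random forest.

    ``splits`` may be supplied to reuse identical folds across several
    evaluations (paired comparisons); ``feature_subset`` restricts the
    columns while keeping rows and splits fixed.
    """
    config = config or RFConfig()
    classes = pd.unique(matrix.y)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    X = matrix.X[feature_subset] if feature_subset is not None else matrix.X
    Xv, yv = X.values, matrix.y.values
    pos = config.positive_class
    if pos not in classes:
        raise ValueError(f"positive class {pos!r} not present")
    if splits is None:
        splits = _cv_splits(matrix, config)

    rows = []
    TP = FP = TN = FN = 0
    for k, (tr, te) in enumerate(splits):
        model = _make_pipeline(config)
        model.fit(Xv[tr], yv[tr])
        pred = model.predict(Xv[te])
        truth = yv[te]
        tp = int(np.sum((pred == pos) & (truth == pos)))
        fp = int(np.sum((pred == pos) & (truth != pos)))
        tn = int(np.sum((pred != pos) & (truth != pos)))
        fn = int(np.sum((pred != pos) & (truth == pos)))
        acc, sens, spec = evaluate_counts(tp, fp, tn, fn)
        rows.append({"fold": k, "accuracy": acc, "sensitivity": sens, "specificity": spec})
        TP, FP, TN, FN = TP + tp, FP + fp, TN + tn, FN + fn
    per_fold = pd.DataFrame(rows)
    return ClassificationReport(
        accuracy=float(per_fold["accuracy"].mean()),
        sensitivity=float(per_fold["sensitivity"].mean()),
        specificity=float(per_fold["specificity"].mean()),
        tp=TP,
        fp=FP,
        tn=TN,
        fn=FN,
        per_fold=per_fold,
        positive_class=pos,
    )


def permutation_importance(matrix: FeatureMatrix, config: RFConfig | None = None) -> pd.DataFrame:
    """Held-out permutation importances, ranked.

    The model is trained on a stratified split and each feature is permuted
    ``n_permutations`` times on the held-out part; the importance is the
    mean accuracy drop.  Ties are broken by feature name so ranks are
    deterministic.
    """
    config = config or RFConfig()
    seed = config.seed % (2**31)
    Xtr, Xte, ytr, yte = train_test_split(
        matrix.X.values,
        matrix.y.values,
        test_size=config.holdout_fraction,
        stratify=matrix.y.values,
        random_state=seed,
    )
    model = _make_pipeline(config)
    model.fit(Xtr, ytr)
    res = _sk_permutation_importance(
        model, Xte, yte,
        scoring="accuracy",
        n_repeats=config.n_permutations,
        random_state=seed,
    )
    df = pd.DataFrame(
        {
            "feature": matrix.X.columns,
            "importance_mean": res.importances_mean,
            "importance_sd": res.importances_std,
        }
    )
    df = df.sort_values(
        ["importance_mean", "feature"], ascending=[False, True]
    ).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df


def progressive_input(
    matrix: FeatureMatrix,
    ordered_groups: list[tuple[str, list[str]]],
    config: RFConfig | None = None,
) -> pd.DataFrame:
    """Evaluate cumulative prefixes of feature groups on identical folds.

    Mirrors a step-wise data input experiment: the first row uses only the
    first group, the second row the first two groups, and so on.  All rows
    share the same cross-validation splits, so differences between rows
    are paired.
    """
    if not ordered_groups:
        raise ValueError("ordered_groups must not be empty")
    config = config or RFConfig()
    for _, feats in ordered_groups:
        missing = set(feats) - set(matrix.X.columns)
        if missing:
            raise KeyError(f"unknown features {sorted(missing)}")
    splits = _cv_splits(matrix, config)
    rows = []
    cumulative: list[str] = []
    for name, feats in ordered_groups:
        cumulative = cumulative + [f for f in feats if f not in cumulative]
        rep = train_and_evaluate(matrix, config, splits=splits, feature_subset=cumulative)
        rows.append(
            {
                "groups": name,
                "n_features": len(cumulative),
                "accuracy": rep.accuracy,
                "sensitivity": rep.sensitivity,
                "specificity": rep.specificity,
            }
        )
    out = pd.DataFrame(rows)
    out["groups"] = [
        " + ".join(g for g, _ in ordered_groups[: i + 1]) for i in range(len(ordered_groups))
    ]
    return out
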