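"""Classification of exams from evolution-curve feature matrices.

Four models are trained on the same rows and columns: Gaussian Naive Bayes and
logistic regression (both on z-scored features, scaler fit on the training
rows only), a 100-tree Random Forest on the raw features, and a soft-voting
ensemble whose class-1 score is the arithmetic mean of the NB and RF class-1
probabilities (soft voting is required for the ensemble to have a continuous
ROC distinct from its members).  Hard labels use a 0.5 probability threshold.

Also provides the stratified 80/20 split, stratified 5-fold cross-validation,
impurity-based feature importance, and the incremental time-point sweep that
re-trains on the first k frames of each curve.
"""

from __future__ import annotations

import dataclasses
import warnings
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.preprocessing import StandardScaler

from .features import AVE_CURVES, FeatureMatrix, assemble_feature_matrix
from .metrics import ClassifierReport, ConfusionMatrix, roc_auc

__all__ = [
    "MODEL_NAMES",
    "SplitSpec",
    "ModelBundle",
    "split_cohort",
    "train_models",
    "evaluate_bundle",
    "cross_validate",
    "timepoint_sweep",
    "feature_importance",
]

MODEL_NAMES = ("naive_bayes", "random_forest", "voting", "logistic_regression")


@dataclasses.dataclass(frozen=True)
class SplitSpec:
    """Train/validation partitioning rules."""

    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 0
    n_folds: int = 5


def split_cohort(matrix: FeatureMatrix, spec: SplitSpec) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Deterministic (seeded) train/validation split, stratified by default."""
    y = matrix.y
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2 or counts.min() < 2:
        raise ValueError("need at least 2 exams per class to split")
    idx = np.arange(matrix.n_samples)
    tr, va = train_test_split(
        idx,
        test_size=1.0 - spec.train_fraction,
        random_state=spec.seed,
        stratify=y if spec.stratified else None,
        shuffle=True,
    )
    train, val = matrix.subset(np.sort(tr)), matrix.subset(np.sort(va))
    if spec.stratified:
        for part, name in ((train, "training"), (val, "validation")):
            if np.unique(part.y).size < 2:
                raise ValueError(f"a class is absent from the {name} split")
    return train, val


@dataclasses.dataclass
class ModelBundle:
    """Fitted models sharing one training split and one standardiser."""

    nb: GaussianNB
    rf: RandomForestClassifier
    logreg: LogisticRegression
    scaler: StandardScaler
    columns: list[str]
    dropped_columns: list[str]
    seed: int

    def predict_proba(self, X: pd.DataFrame) -> dict[str, np.ndarray]:
        """Class-1 probability per model; the voting score is the exact mean
        of the NB and RF probabilities."""
        Xr = X[self.columns].to_numpy(dtype=float)
        Xs = self.scaler.transform(Xr)
        p = {
            "naive_bayes": self.nb.predict_proba(Xs)[:, 1],
            "random_forest": self.rf.predict_proba(Xr)[:, 1],
            "logistic_regression": self.logreg.predict_proba(Xs)[:, 1],
        }
        p["voting"] = 0.5 * (p["naive_bayes"] + p["random_forest"])
        return p


def train_models(train: FeatureMatrix, seed: int = 0) -> ModelBundle:
    """Fit NB, RF, logistic regression and the voting ensemble.

    Standardisation is fit on the training rows only (no leakage).  Constant
    training columns are dropped with a warning; NB additionally applies its
    variance floor of 1e-9 times the largest column variance.
    """
    if np.unique(train.y).size < 2:
        raise ValueError("training data must contain both classes")
    X = train.X
    const = X.columns[X.nunique() <= 1].tolist()
    if const:
        warnings.warn(
            f"dropping {len(const)} constant training column(s): {const[:5]}...",
            stacklevel=2,
        )
        X = X.drop(columns=const)
    if X.shape[1] == 0:
        raise ValueError("no informative columns remain after dropping constants")

    Xr = X.to_numpy(dtype=float)
    scaler = StandardScaler().fit(Xr)
    Xs = scaler.transform(Xr)
    nb = GaussianNB().fit(Xs, train.y)  # var_smoothing = 1e-9 * max column variance
    rf = RandomForestClassifier(n_estimators=100, random_state=seed).fit(Xr, train.y)
    logreg = LogisticRegression(C=1.0, max_iter=2000).fit(Xs, train.y)  # L2, unit strength
    return ModelBundle(
        nb=nb,
        rf=rf,
        logreg=logreg,
        scaler=scaler,
        columns=X.columns.tolist(),
        dropped_columns=const,
        seed=seed,
    )


def evaluate_bundle(
    bundle: ModelBundle, data: FeatureMatrix, dataset: str = "validation"
) -> dict[str, ClassifierReport]:
    """Confusion metrics and ROC/AUC per model at the 0.5 probability threshold.

    Single-class data yields reports with the AUC missing rather than an error.
    """
    if data.n_samples == 0:
        raise ValueError("empty evaluation data")
    y = data.y
    probs = bundle.predict_proba(data.X)
    both_classes = np.unique(y).size == 2
    out: dict[str, ClassifierReport] = {}
    for name in MODEL_NAMES:
        p = probs[name]
        pred = (p >= 0.5).astype(int)
        cm = ConfusionMatrix(
            tp=int(((pred == 1) & (y == 1)).sum()),
            fp=int(((pred == 1) & (y == 0)).sum()),
            tn=int(((pred == 0) & (y == 0)).sum()),
            fn=int(((pred == 0) & (y == 1)).sum()),
        )
        roc = roc_auc(p, y, auto_orient=False) if both_classes else None
        out[name] = ClassifierReport.from_confusion(cm, model=name, dataset=dataset, roc=roc)
    return out


def cross_validate(matrix: FeatureMatrix, spec: SplitSpec) -> pd.DataFrame:
    """Stratified k-fold validation AUC per model (rows = folds)."""
    skf = StratifiedKFold(n_splits=spec.n_folds, shuffle=True, random_state=spec.seed)
    rows = []
    for tr, va in skf.split(matrix.X, matrix.y):
        bundle = train_models(matrix.subset(tr), seed=spec.seed)
        probs = bundle.predict_proba(matrix.subset(va).X)
        yv = matrix.y[va]
        rows.append(
            {
                name: roc_auc(probs[name], yv, auto_orient=False).auc
                if np.unique(yv).size == 2
                else np.nan
                for name in MODEL_NAMES
            }
        )
    return pd.DataFrame(rows)


def timepoint_sweep(
    cohort: Iterable,
    k_list: Sequence[int],
    spec: SplitSpec | None = None,
    seed: int = 0,
    curve_subset: Sequence[str] = AVE_CURVES,
) -> pd.DataFrame:
    """Validation AUC per model as the first k time points are incorporated.

    Re-assembles the feature matrix, re-splits and re-trains for every k;
    returns a DataFrame indexed by k with one column per model.
    """
    k_list = list(k_list)
    if not k_list:
        raise ValueError("k_list must not be empty")
    spec = spec or SplitSpec(seed=seed)
    items = list(cohort)
    rows = {}
    for k in k_list:
        fm = assemble_feature_matrix(items, curve_subset=curve_subset, k=k)
        train, val = split_cohort(fm, spec)
        bundle = train_models(train, seed=seed)
        reports = evaluate_bundle(bundle, val)
        rows[k] = {name: reports[name].auc for name in MODEL_NAMES}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "k"
    return df


def feature_importance(bundle: ModelBundle) -> list[tuple[str, float]]:
    """Impurity-based RF importances, normalised to sum to 1, ranked
    descending with ties broken by column order."""
    imp = np.asarray(bundle.rf.feature_importances_, dtype=float)
    s = imp.sum()
    if s > 0:
        imp = imp / s
    order = np.argsort(-imp, kind="stable")
    return [(bundle.columns[i], float(imp[i])) for i in order]
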