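"""Gradient-boosted TES classifier on NES features.

An XGBoost model (binary logistic objective) predicts the TES label of a
sample from its gene-set NES vector, so new patients can be subtyped
without re-clustering.  Evaluation uses stratified k-fold cross-validation
(10 folds by default); both the mean per-fold accuracy and the
pooled-prediction accuracy are reported, together with the pooled confusion
matrix and ROC AUC.  Feature importance is the mean absolute SHAP value per
gene set, computed with XGBoost's native TreeSHAP (``pred_contribs``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from itertools import product
from pathlib import Path

import json
import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.metrics import confusion_matrix, roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .errors import SchemaError, TesError
from .geneset_scoring import NESMatrix


@dataclass(frozen=True)
class ClassifierSpec:
    """XGBoost hyperparameters; defaults are the grid-search winners."""

    learning_rate: float = 0.1
    n_estimators: int = 100
    max_depth: int = 3
    colsample_bytree: float = 0.8
    objective: str = "binary:logistic"
    random_state: int = 123
    cv_folds: int = 10

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.n_estimators, self.max_depth,
               self.colsample_bytree) <= 0:
            raise ValueError("all hyperparameters must be positive")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")


#: grid searched by --tune (learning rate x trees x depth x column subsample)
TUNING_GRID = {
    "learning_rate": (0.1, 0.01, 0.001),
    "n_estimators": (50, 100, 200),
    "max_depth": (3, 6, 9),
    "colsample_bytree": (0.6, 0.8, 1.0),
}


@dataclass
class EvaluationReport:
    cv_fold_accuracies: list[float]
    cv_accuracy_mean: float   # mean of per-fold accuracies
    cv_accuracy_pooled: float  # accuracy of pooled out-of-fold predictions
    confusion: pd.DataFrame = field(repr=False)
    roc_auc: float = float("nan")
    feature_importance: pd.Series = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "cv_fold_accuracies": self.cv_fold_accuracies,
            "cv_accuracy_mean": self.cv_accuracy_mean,
            "cv_accuracy_pooled": self.cv_accuracy_pooled,
            "confusion": self.confusion.to_dict(),
            "roc_auc": self.roc_auc,
            "feature_importance": (self.feature_importance.to_dict()
                                   if self.feature_importance is not None else None),
        }


@dataclass
class TesClassifier:
    """Fitted booster plus the feature/label manifest needed for prediction.

    The underlying model is kept as an ``xgb.Booster`` so that saved models
    reload independently of the scikit-learn wrapper state.
    """

    model: xgb.Booster = field(repr=False)
    feature_names: list[str] = field(default_factory=list)
    classes: list[int] = field(default_factory=list)  # TES labels in encoded order
    spec: ClassifierSpec = field(default_factory=ClassifierSpec)

    def save(self, model_path: str | Path, manifest_path: str | Path | None = None) -> None:
        model_path = Path(model_path)
        self.model.save_model(model_path)
        manifest = {
            "feature_names": self.feature_names,
            "classes": self.classes,
            "spec": asdict(self.spec),
        }
        if manifest_path is None:
            manifest_path = model_path.with_suffix(".manifest.json")
        Path(manifest_path).write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, model_path: str | Path, manifest_path: str | Path | None = None
             ) -> "TesClassifier":
        model_path = Path(model_path)
        if manifest_path is None:
            manifest_path = model_path.with_suffix(".manifest.json")
        manifest = json.loads(Path(manifest_path).read_text())
        spec = ClassifierSpec(**manifest["spec"])
        booster = xgb.Booster()
        booster.load_model(str(model_path))
        return cls(model=booster, feature_names=manifest["feature_names"],
                   classes=manifest["classes"], spec=spec)


def _make_model(spec: ClassifierSpec) -> xgb.XGBClassifier:
    return xgb.XGBClassifier(
        learning_rate=spec.learning_rate,
        n_estimators=spec.n_estimators,
        max_depth=spec.max_depth,
        colsample_bytree=spec.colsample_bytree,
        objective=spec.objective,
        random_state=spec.random_state,
        n_jobs=1,
    )


def _features(nes: NESMatrix | pd.DataFrame) -> pd.DataFrame:
    return nes.scores if isinstance(nes, NESMatrix) else nes


def train_cv(
    nes: NESMatrix | pd.DataFrame,
    labels: pd.Series,
    spec: ClassifierSpec = ClassifierSpec(),
) -> tuple[TesClassifier, EvaluationReport]:
    """Stratified k-fold CV evaluation, then a refit on all samples.

    Labels are the (1-based) TES labels; they are encoded to 0..k-1
    internally.  Raises when any class has fewer samples than folds.
    """
    x = _features(nes)
    labels = labels.loc[x.index]
    classes = sorted(labels.unique())
    counts = labels.value_counts()
    if (counts < spec.cv_folds).any():
        small = counts[counts < spec.cv_folds]
        raise ValueError(
            f"class(es) {list(small.index)} have fewer samples than cv_folds={spec.cv_folds}")
    enc = {c: i for i, c in enumerate(classes)}
    y = labels.map(enc).to_numpy()
    X = x.to_numpy(dtype=float)

    skf = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True,
                          random_state=spec.random_state)
    fold_acc: list[float] = []
    pooled_pred = np.empty_like(y)
    pooled_prob = np.empty((len(y), len(classes)))
    for train_idx, test_idx in skf.split(X, y):
        m = _make_model(spec)
        m.fit(X[train_idx], y[train_idx])
        prob = m.predict_proba(X[test_idx])
        pred = prob.argmax(axis=1)
        pooled_pred[test_idx] = pred
        pooled_prob[test_idx] = prob
        fold_acc.append(float((pred == y[test_idx]).mean()))

    conf = pd.DataFrame(
        confusion_matrix(y, pooled_pred, labels=range(len(classes))),
        index=pd.Index(classes, name="true"),
        columns=pd.Index(classes, name="predicted"),
    )
    if len(classes) == 2:
        auc = float(roc_auc_score(y, pooled_prob[:, 1]))
    else:
        auc = float(roc_auc_score(y, pooled_prob, multi_class="ovr"))

    final = _make_model(spec)
    final.fit(X, y)
    clf = TesClassifier(model=final.get_booster(), feature_names=list(x.columns),
                        classes=[int(c) for c in classes], spec=spec)
    report = EvaluationReport(
        cv_fold_accuracies=fold_acc,
        cv_accuracy_mean=float(np.mean(fold_acc)),
        cv_accuracy_pooled=float((pooled_pred == y).mean()),
        confusion=conf,
        roc_auc=auc,
        feature_importance=feature_importance(clf, x),
    )
    return clf, report


def predict(clf: TesClassifier, nes: NESMatrix | pd.DataFrame
            ) -> tuple[pd.Series, pd.DataFrame]:
    """Predict TES labels for new samples; features are aligned by name.

    Column order of the input is irrelevant; missing or extra feature names
    are a schema error listing the mismatch.
    """
    x = _features(nes)
    missing = [f for f in clf.feature_names if f not in x.columns]
    extra = [f for f in x.columns if f not in clf.feature_names]
    if missing or extra:
        raise SchemaError(f"feature mismatch: missing={missing}, extra={extra}")
    x = x[clf.feature_names]
    raw = clf.model.predict(xgb.DMatrix(x.to_numpy(dtype=float)))
    prob = np.column_stack([1.0 - raw, raw]) if raw.ndim == 1 else raw
    labels = pd.Series([clf.classes[i] for i in prob.argmax(axis=1)],
                       index=x.index, name="tes_label")
    probs = pd.DataFrame(prob, index=x.index,
                         columns=[f"p_tes{c}" for c in clf.classes])
    return labels, probs


def feature_importance(clf: TesClassifier, features: pd.DataFrame,
                       top: int | None = None) -> pd.Series:
    """Mean absolute SHAP value per gene set, descending.

    Attributions are XGBoost's native TreeSHAP contributions evaluated on
    ``features`` (normally the training cohort's NES matrix); the bias
    column is dropped before averaging.
    """
    if clf.model is None or not clf.model.num_boosted_rounds():
        raise TesError("model is not fitted")
    x = features[clf.feature_names].to_numpy(dtype=float)
    contribs = clf.model.predict(xgb.DMatrix(x), pred_contribs=True)
    if contribs.ndim == 3:  # multiclass: (n, classes, features+1)
        contribs = np.abs(contribs).mean(axis=1)
    imp = pd.Series(np.abs(contribs[:, :-1]).mean(axis=0),  # drop bias column
                    index=clf.feature_names, name="mean_abs_shap")
    imp = imp.sort_values(ascending=False)
    return imp.head(top) if top else imp


def tune(
    nes: NESMatrix | pd.DataFrame,
    labels: pd.Series,
    base: ClassifierSpec = ClassifierSpec(),
    grid: dict = TUNING_GRID,
) -> tuple[ClassifierSpec, pd.DataFrame]:
    """Grid search over the hyperparameter grid by mean CV accuracy."""
    rows = []
    best_spec, best_acc = None, -1.0
    keys = list(grid)
    for combo in product(*(grid[k] for k in keys)):
        params = dict(zip(keys, combo))
        spec = ClassifierSpec(**{**asdict(base), **params})
        _, report = train_cv(nes, labels, spec)
        rows.append({**params, "cv_accuracy_mean": report.cv_accuracy_mean})
        if report.cv_accuracy_mean > best_acc:
            best_acc, best_spec = report.cv_accuracy_mean, spec
    return best_spec, pd.DataFrame(rows)
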