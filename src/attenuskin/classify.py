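"""Linear-SVM classification of binned OCT features.

Ten-fold (stratified, seeded) cross-validation with out-of-fold
predictions pooled for the overall accuracy and per-sample report,
per-fold ROC curves interpolated onto a common FPR grid for the mean
ROC +/- SD, and the feature weight vector from a final refit on all data.
MM is the positive class so weight signs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import auc, confusion_matrix, roc_curve
from sklearn.model_selection import StratifiedKFold, KFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .binning import FEATURE_NAMES

__all__ = [
    "CvConfig",
    "ClassificationReport",
    "cross_validate",
    "per_sample_report",
    "extract_weights",
    "POSITIVE_CLASS",
]

POSITIVE_CLASS = "MM"
ROC_GRID_POINTS = 101


@dataclass(frozen=True)
class CvConfig:
    n_folds: int = 10
    kernel: str = "linear"
    regularization_C: float = 1.0
    feature_subset: tuple[str, ...] = FEATURE_NAMES
    seed: int = 0
    stratified: bool = True
    standardize: bool = True

    def validate(self, available: tuple[str, ...] = FEATURE_NAMES) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not self.regularization_C > 0:
            raise ValueError("regularization_C must be positive")
        if self.kernel != "linear":
            raise ValueError("only the linear kernel is supported")
        unknown = [f for f in self.feature_subset if f not in available]
        if unknown:
            raise ValueError(f"unknown features: {unknown}")


@dataclass
class ClassificationReport:
    fold_accuracies: np.ndarray
    overall_accuracy: float
    confusion: np.ndarray  # rows true (BN, MM), cols predicted
    class_order: tuple[str, str]
    fpr_grid: np.ndarray
    mean_tpr: np.ndarray
    tpr_sd: np.ndarray
    fold_aucs: np.ndarray
    mean_auc: float
    auc_sd: float
    weights: dict[str, float]
    per_sample: pd.DataFrame
    oof_predictions: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "overall_accuracy": float(self.overall_accuracy),
            "confusion_matrix": self.confusion.astype(int).tolist(),
            "class_order": list(self.class_order),
            "fpr_grid": self.fpr_grid.tolist(),
            "mean_tpr": self.mean_tpr.tolist(),
            "tpr_sd": self.tpr_sd.tolist(),
            "fold_aucs": [float(a) for a in self.fold_aucs],
            "mean_auc": float(self.mean_auc),
            "auc_sd": float(self.auc_sd),
            "weights": {k: float(v) for k, v in self.weights.items()},
            "per_sample": self.per_sample.to_dict(orient="records"),
        }


def _make_svm(cfg: CvConfig) -> SVC:
    return SVC(kernel="linear", C=cfg.regularization_C)


def _fit_fold(x_tr, y_tr, x_te, cfg: CvConfig):
    if cfg.standardize:
        scaler = StandardScaler().fit(x_tr)
        x_tr = scaler.transform(x_tr)
        x_te = scaler.transform(x_te)
    clf = _make_svm(cfg).fit(x_tr, y_tr)
    return clf.predict(x_te), clf.decision_function(x_te)


def interpolate_roc(
    scores: np.ndarray, y_true: np.ndarray, fpr_grid: np.ndarray
) -> tuple[np.ndarray, float]:
    """One fold's ROC resampled onto the common FPR grid, plus its AUC."""
    fpr, tpr, _ = roc_curve(y_true, scores)
    fold_auc = auc(fpr, tpr)
    tpr_i = np.interp(fpr_grid, fpr, tpr)
    tpr_i[0] = 0.0
    tpr_i[-1] = 1.0
    return tpr_i, float(fold_auc)


def cross_validate(features: pd.DataFrame, cfg: CvConfig | None = None) -> ClassificationReport:
    """Stratified k-fold CV of a linear SVM on the binned feature table.

    ``features`` must carry the numeric feature columns plus ``label``
    (BN/MM) and ``sample_id``.
    """
    cfg = cfg or CvConfig()
    available = tuple(
        c for c in features.columns if c not in ("label", "sample_id", "bin_index")
    )
    cfg.validate(available)
    labels = features["label"].to_numpy()
    classes = sorted(set(labels), key=lambda c: (c == POSITIVE_CLASS, c))
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {classes}")
    neg, pos = classes[0], classes[1]
    if POSITIVE_CLASS in classes:
        pos = POSITIVE_CLASS
        neg = classes[0] if classes[1] == POSITIVE_CLASS else classes[1]
    x = features[list(cfg.feature_subset)].to_numpy(dtype=float)
    y = (labels == pos).astype(int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < cfg.n_folds:
        raise ValueError("each class needs at least n_folds members")

    splitter_cls = StratifiedKFold if cfg.stratified else KFold
    splitter = splitter_cls(n_splits=cfg.n_folds, shuffle=True, random_state=cfg.seed)

    n = len(y)
    oof_pred = np.empty(n, dtype=int)
    oof_score = np.empty(n, dtype=float)
    fpr_grid = np.linspace(0.0, 1.0, ROC_GRID_POINTS)
    fold_acc, fold_aucs, tprs = [], [], []
    for tr, te in splitter.split(x, y):
        pred, score = _fit_fold(x[tr], y[tr], x[te], cfg)
        oof_pred[te] = pred
        oof_score[te] = score
        fold_acc.append(float(np.mean(pred == y[te])))
        tpr_i, fold_auc = interpolate_roc(score, y[te], fpr_grid)
        tprs.append(tpr_i)
        fold_aucs.append(fold_auc)

    tprs = np.vstack(tprs)
    fold_aucs = np.asarray(fold_aucs)
    overall = float(np.mean(oof_pred == y))
    cm = confusion_matrix(y, oof_pred, labels=[0, 1])

    # final refit on all rows for the weight vector
    x_final = x
    if cfg.standardize:
        x_final = StandardScaler().fit_transform(x)
    final_model = _make_svm(cfg).fit(x_final, y)
    weights = extract_weights(final_model, cfg.feature_subset)

    oof = pd.DataFrame(
        {
            "sample_id": features["sample_id"].to_numpy(),
            "label": labels,
            "predicted": np.where(oof_pred == 1, pos, neg),
            "score": oof_score,
        }
    )
    per_sample = per_sample_report(
        oof["predicted"].to_numpy(), oof["sample_id"].to_numpy(), labels
    )
    return ClassificationReport(
        fold_accuracies=np.asarray(fold_acc),
        overall_accuracy=overall,
        confusion=cm,
        class_order=(neg, pos),
        fpr_grid=fpr_grid,
        mean_tpr=tprs.mean(axis=0),
        tpr_sd=tprs.std(axis=0, ddof=0),
        fold_aucs=fold_aucs,
        mean_auc=float(fold_aucs.mean()),
        auc_sd=float(fold_aucs.std(ddof=0)),
        weights=weights,
        per_sample=per_sample,
        oof_predictions=oof,
    )


def per_sample_report(
    predictions: np.ndarray, sample_ids: np.ndarray, labels: np.ndarray
) -> pd.DataFrame:
    """Per-sample correct counts, proportions, and majority verdicts.

    An instance is correct when its out-of-fold prediction matches the
    sample's true label; the verdict is ``correct`` when more than half
    the sample's instances are.
    """
    predictions = np.asarray(predictions)
    sample_ids = np.asarray(sample_ids)
    labels = np.asarray(labels)
    if not (len(predictions) == len(sample_ids) == len(labels)):
        raise ValueError("predictions, sample_ids, labels must align")
    rows = []
    for sid in pd.unique(sample_ids):
        mask = sample_ids == sid
        total = int(mask.sum())
        correct = int(np.sum(predictions[mask] == labels[mask]))
        proportion = correct / total
        rows.append(
            {
                "sample_id": sid,
                "total": total,
                "correct": correct,
                "proportion": proportion,
                "verdict": "correct" if proportion > 0.5 else "wrong-type",
            }
        )
    return pd.DataFrame(rows)


def extract_weights(model: SVC, feature_names) -> dict[str, float]:
    """Signed linear-SVM coefficients keyed by feature name."""
    if getattr(model, "kernel", None) != "linear":
        raise ValueError("weight extraction requires a linear kernel")
    coef = np.asarray(model.coef_).ravel()
    names = list(feature_names)
    if coef.size != len(names):
        raise ValueError("feature-name count does not match coefficients")
    return {name: float(w) for name, w in zip(names, coef)}
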