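"""Per-patient SVM-RBF segmentation of tumor vs healthy pixels.

Protocol: pixels are split at random into train (20%), test (20%) and
validation (60%); within train and test the larger class is randomly
down-sampled so both classes have equal counts.  An RBF-kernel SVM is
trained on the balanced train set after train-statistics-only median
imputation and z-scoring; generalization is checked by 10-fold
cross-validation over the balanced train+test pool, and the headline
accuracy / sensitivity / specificity are computed on the untouched
(unbalanced) validation set.

Four model families share this protocol, differing only in their feature
columns: TD_BL, TD_BL+REC, FD_BL, FD_BL+REC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.impute import SimpleImputer
from sklearn.model_selection import KFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, validate_data

from .features.td import TD_BL_FEATURES, TD_REC_FEATURES

__all__ = [
    "FAMILIES", "family_columns", "SplitPlan", "make_split",
    "PixelSVMSegmenter", "train_model", "evaluate", "SegmentationResult",
    "confusion_metrics",
]

FAMILIES = ("td_bl", "td_bl+rec", "fd_bl", "fd_bl+rec")


def family_columns(family: str, table: pd.DataFrame) -> list[str]:
    """Feature columns of a model family, checked against the table."""
    if family == "td_bl":
        cols = list(TD_BL_FEATURES)
    elif family == "td_bl+rec":
        cols = list(TD_BL_FEATURES) + list(TD_REC_FEATURES)
    elif family == "fd_bl":
        cols = [c for c in table.columns if c.startswith("wcoh_bl_")]
    elif family == "fd_bl+rec":
        cols = [c for c in table.columns
                if c.startswith("wcoh_bl_") or c.startswith("wcoh_rec_")]
    else:
        raise ValueError(f"unknown model family {family!r}")
    missing = [c for c in cols if c not in table.columns]
    if missing or not cols:
        raise ValueError(f"table lacks columns for family {family!r}: "
                         f"{missing or 'no coherence columns found'}")
    return cols


# -- split ------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Random 20/20/60 pixel split with class-balanced train and test.

    ``train_idx``/``test_idx`` are the post-balancing row indices;
    ``train_idx_all``/``test_idx_all`` the pre-balancing ones, so that
    ``train_idx_all + test_idx_all + validation_idx`` partitions the rows.
    """

    train_idx: np.ndarray
    test_idx: np.ndarray
    validation_idx: np.ndarray
    train_idx_all: np.ndarray
    test_idx_all: np.ndarray
    seed: int
    balance_record: dict = field(default_factory=dict)


def _balance(idx: np.ndarray, labels: np.ndarray,
             rng: np.random.Generator) -> np.ndarray:
    """Randomly down-sample the larger class within ``idx``."""
    cls = labels[idx]
    keep = []
    n_min = min(int((cls == 0).sum()), int((cls == 1).sum()))
    for c in (0, 1):
        members = idx[cls == c]
        if members.size > n_min:
            members = rng.choice(members, size=n_min, replace=False)
        keep.append(members)
    return np.sort(np.concatenate(keep))


def make_split(labels, train_frac: float = 0.2, test_frac: float = 0.2,
               seed: int = 0) -> SplitPlan:
    """Uniform random train/test/validation split with balancing.

    Raises if a class is missing from the data or from the raw train split
    (re-seed in that case).
    """
    labels = np.asarray(labels)
    if train_frac <= 0 or test_frac <= 0 or train_frac + test_frac >= 1:
        raise ValueError("train and test fractions must be positive and sum "
                         "to less than 1")
    if not ((labels == 0).any() and (labels == 1).any()):
        raise ValueError("both classes must be present")
    n = labels.size
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(train_frac * n))
    n_test = int(round(test_frac * n))
    train_all = np.sort(perm[:n_train])
    test_all = np.sort(perm[n_train:n_train + n_test])
    val = np.sort(perm[n_train + n_test:])
    for name, idx in (("train", train_all), ("test", test_all)):
        if len(np.unique(labels[idx])) < 2:
            raise ValueError(f"class missing from the {name} split; "
                             "choose another seed")
    train = _balance(train_all, labels, rng)
    test = _balance(test_all, labels, rng)
    record = {}
    for name, before, after in (("train", train_all, train),
                                ("test", test_all, test)):
        record[name] = {
            "before": {c: int((labels[before] == c).sum()) for c in (0, 1)},
            "after": {c: int((labels[after] == c).sum()) for c in (0, 1)},
        }
    return SplitPlan(train_idx=train, test_idx=test, validation_idx=val,
                     train_idx_all=train_all, test_idx_all=test_all,
                     seed=seed, balance_record=record)


# -- model ------------------------------------------------------------------

class PixelSVMSegmenter(ClassifierMixin, BaseEstimator):
    """RBF-kernel SVM over per-pixel features, as a sklearn classifier.

    Median imputation (for pixels whose recovery fit was rejected) and
    z-scoring are fit on the training data only and reapplied at prediction
    time; both run inside every cross-validation fold when the estimator is
    cloned, so no statistics leak across folds.
    """

    def __init__(self, C: float = 1.0, gamma="scale",
                 impute_strategy: str = "median", standardize: bool = True):
        self.C = C
        self.gamma = gamma
        self.impute_strategy = impute_strategy
        self.standardize = standardize

    def _build(self) -> Pipeline:
        steps = [("impute", SimpleImputer(strategy=self.impute_strategy,
                                          keep_empty_features=True))]
        if self.standardize:
            steps.append(("scale", StandardScaler()))
        steps.append(("svm", SVC(C=self.C, gamma=self.gamma, kernel="rbf")))
        return Pipeline(steps)

    def fit(self, X, y):
        X, y = validate_data(self, X, y, ensure_all_finite="allow-nan")
        if np.isnan(X).all(axis=0).any():
            warnings.warn("feature column(s) with no observed values are "
                          "imputed as constants and carry no information")
        self.pipeline_ = self._build().fit(X, y)
        self.classes_ = self.pipeline_[-1].classes_
        return self

    def predict(self, X):
        check_is_fitted(self, "pipeline_")
        X = validate_data(self, X, reset=False, ensure_all_finite="allow-nan")
        return self.pipeline_.predict(X)

    def decision_function(self, X):
        check_is_fitted(self, "pipeline_")
        X = validate_data(self, X, reset=False, ensure_all_finite="allow-nan")
        return self.pipeline_.decision_function(X)


def train_model(table: pd.DataFrame, split: SplitPlan, family: str,
                **svm_params) -> PixelSVMSegmenter:
    """Fit a family's SVM on the balanced training pixels of ``table``."""
    cols = family_columns(family, table)
    X = table[cols].to_numpy(dtype=float)
    y = table["label"].to_numpy()
    model = PixelSVMSegmenter(**svm_params)
    model.fit(X[split.train_idx], y[split.train_idx])
    model.feature_columns_ = cols
    model.family_ = family
    return model


# -- evaluation -------------------------------------------------------------

def confusion_metrics(y_true, y_pred) -> dict:
    """Accuracy, sensitivity (TPR on tumor), specificity (TNR on healthy),
    in percent, plus the confusion counts.  Metrics whose denominator is
    empty come back NaN."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    total = tp + tn + fp + fn

    def pct(num, den):
        return 100.0 * num / den if den else float("nan")

    return {"accuracy": pct(tp + tn, total),
            "sensitivity": pct(tp, tp + fn),
            "specificity": pct(tn, tn + fp),
            "tp": tp, "tn": tn, "fp": fp, "fn": fn}


@dataclass
class SegmentationResult:
    """Validation-set metrics (percent), CV scores and the prediction map."""

    model_family: str
    accuracy: float
    sensitivity: float
    specificity: float
    confusion: dict
    cv_scores: np.ndarray
    prediction_map: np.ndarray
    hyperparams: dict
    seed: int


def evaluate(model: PixelSVMSegmenter, table: pd.DataFrame, split: SplitPlan,
             frame_shape: tuple[int, int] | None = None,
             n_folds: int = 10) -> SegmentationResult:
    """Validation-set metrics plus k-fold CV over the balanced train+test pool.

    The prediction map covers every pixel (train/test pixels included).
    """
    cols = model.feature_columns_
    X = table[cols].to_numpy(dtype=float)
    y = table["label"].to_numpy()

    metrics = confusion_metrics(y[split.validation_idx],
                                model.predict(X[split.validation_idx]))

    pool = np.concatenate([split.train_idx, split.test_idx])
    cv = KFold(n_splits=n_folds, shuffle=True, random_state=split.seed)
    cv_scores = cross_val_score(clone(model), X[pool], y[pool], cv=cv)

    pred_all = model.predict(X)
    if frame_shape is not None:
        pred_map = pred_all.reshape(frame_shape)
    else:
        pred_map = pred_all
    return SegmentationResult(
        model_family=model.family_,
        accuracy=metrics["accuracy"], sensitivity=metrics["sensitivity"],
        specificity=metrics["specificity"],
        confusion={k: metrics[k] for k in ("tp", "tn", "fp", "fn")},
        cv_scores=np.asarray(cv_scores), prediction_map=pred_map,
        hyperparams={"C": model.C, "gamma": model.gamma}, seed=split.seed)
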