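"""Malignancy classification from the single fractal-dimension feature.

Three experiments are supported, mirroring the standard evaluation design
for single-feature slide classifiers:

* binary benign/malignant with a stratified random half used for training;
* 8-way tumour-subtype classification (one-vs-rest);
* the 16-combination cross-subtype grid — train on one benign and one
  malignant subtype, test on the six held-out subtypes — probing whether
  the feature generalizes to unseen tumour types.

Metric note: the F1 reported here is the harmonic mean of the
true-positive rate (sensitivity on the malignant class) and the
true-negative rate (specificity on the benign class),

    F1 = 2·TP·TN / (TP + TN).

This is *not* the conventional precision/recall F1; it is kept because it
is the convention of the evaluation this package reproduces.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC

BENIGN_SUBTYPES = ("A", "F", "PT", "TA")
MALIGNANT_SUBTYPES = ("DC", "LC", "MC", "PC")
ALL_SUBTYPES = BENIGN_SUBTYPES + MALIGNANT_SUBTYPES
MAGNIFICATIONS = ("40x", "100x", "200x", "400x")


@dataclass
class FDRecord:
    """One image's identity and its fractal dimension — a feature-table row."""

    image_id: str
    magnification: str
    label: Literal["benign", "malignant"]
    subtype: str
    fd: float

    def __post_init__(self) -> None:
        if self.label not in ("benign", "malignant"):
            raise ValueError(f"unknown label {self.label!r}")
        if self.subtype not in ALL_SUBTYPES:
            raise ValueError(f"unknown subtype {self.subtype!r}")
        benign = self.subtype in BENIGN_SUBTYPES
        if benign != (self.label == "benign"):
            raise ValueError(
                f"subtype {self.subtype} inconsistent with label {self.label}"
            )


@dataclass
class ClassificationReport:
    """Rates and confusion counts for one experiment.

    ``f1`` is the harmonic mean of ``tp_rate`` and ``tn_rate`` (see module
    docstring).  ``confusion`` holds (tp, fn, tn, fp) counts for binary
    runs, or a subtype-indexed matrix for multiclass runs.
    """

    tp_rate: float
    tn_rate: float
    f1: float
    accuracy: float
    confusion: dict
    n_train: int
    n_test: int
    threshold: float | None = None

    def rounded(self, ndigits: int = 3) -> dict:
        """Serialization view with rates rounded to ``ndigits`` decimals."""
        return {
            "tp_rate": round(self.tp_rate, ndigits),
            "tn_rate": round(self.tn_rate, ndigits),
            "f1": round(self.f1, ndigits),
            "accuracy": round(self.accuracy, ndigits),
            "n_train": self.n_train,
            "n_test": self.n_test,
            "threshold": None if self.threshold is None else round(self.threshold, 6),
        }


@dataclass
class SplitSpec:
    """Stratified random-split recipe; the seed is mandatory because a
    split without one is irreproducible."""

    fraction: float = 0.5
    seed: int = 0
    stratify_by: Literal["label", "subtype"] = "label"

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction < 1.0:
            raise ValueError("fraction must lie in (0, 1)")


def harmonic_f1(tp_rate: float, tn_rate: float) -> float:
    """Harmonic mean of sensitivity and specificity; 0 when both are 0."""
    denom = tp_rate + tn_rate
    if denom <= 0:
        return 0.0
    return 2.0 * tp_rate * tn_rate / denom


def split_records(
    records: Sequence[FDRecord], spec: SplitSpec
) -> tuple[list[FDRecord], list[FDRecord]]:
    """Seeded stratified partition into (train, test).

    Within each stratum, floor(fraction·n) records go to train and the
    remainder to test; strata with fewer than 2 records are an error
    because they cannot populate both sides.
    """
    key = (lambda r: r.label) if spec.stratify_by == "label" else (lambda r: r.subtype)
    strata: dict[str, list[FDRecord]] = {}
    for rec in records:
        strata.setdefault(key(rec), []).append(rec)
    rng = np.random.default_rng(spec.seed)
    train: list[FDRecord] = []
    test: list[FDRecord] = []
    for name in sorted(strata):
        members = strata[name]
        if len(members) < 2:
            raise ValueError(f"stratum {name!r} has fewer than 2 records")
        order = rng.permutation(len(members))
        n_train = int(spec.fraction * len(members))
        train.extend(members[i] for i in order[:n_train])
        test.extend(members[i] for i in order[n_train:])
    return train, test


class FractalDimensionClassifier:
    """Binary benign/malignant classifier on the 1-D fd feature.

    A linear SVM on a single feature has a monotone decision function, so
    the fitted model is equivalent to a threshold plus an orientation;
    both are exposed for inspection after fitting.

    Parameters
    ----------
    C : float
        SVM regularization strength (default 1.0).

    Attributes
    ----------
    threshold_ : float
        The fd value at which the decision function crosses zero.
    orientation_ : {+1, -1}
        +1 when fd above the threshold is called malignant, -1 when fd
        below the threshold is called malignant.
    classes_ : ndarray of str
        ``["benign", "malignant"]``.

    Ties (fd exactly at the threshold) are classified malignant — the
    positive class — by convention.
    """

    _POS = "malignant"
    _NEG = "benign"

    def __init__(self, C: float = 1.0):
        self.C = C

    def fit(self, X, y):
        X = np.asarray(X, dtype=float).reshape(-1, 1)
        y = np.asarray(y)
        labels = set(y.tolist())
        if labels != {self._NEG, self._POS}:
            raise ValueError(
                f"training set must contain both classes, got {sorted(labels)}"
            )
        y_num = (y == self._POS).astype(int)
        svm = SVC(kernel="linear", C=self.C)
        svm.fit(X, y_num)
        w = float(svm.coef_[0, 0])
        b = float(svm.intercept_[0])
        if w == 0.0:  # pathological flat decision function
            raise ValueError("degenerate SVM fit: zero weight on the feature")
        self.svm_ = svm
        self.threshold_ = -b / w
        self.orientation_ = 1 if w > 0 else -1
        self.classes_ = np.array([self._NEG, self._POS])
        self.n_features_in_ = 1
        return self

    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float).reshape(-1, 1)
        return self.orientation_ * (X[:, 0] - self.threshold_)

    def predict(self, X) -> np.ndarray:
        score = self.decision_function(X)
        return np.where(score >= 0.0, self._POS, self._NEG)

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))

    def get_params(self, deep: bool = True) -> dict:
        return {"C": self.C}

    def set_params(self, **params):
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self


class SubtypeClassifier:
    """8-way tumour-subtype classifier on the fd feature.

    Pairwise (one-vs-one) linear SVMs with majority voting by default: on
    a single feature each pairwise machine is a threshold, so the voting
    scheme partitions the fd axis into per-subtype intervals.  One-vs-rest
    is kept as an option but is degenerate in 1-D (interior classes can
    never win the argmax); ``scheme="nearest_mean"`` is a plain
    nearest-class-mean baseline for sanity comparisons.
    """

    def __init__(self, C: float = 1.0, scheme: str = "ovo"):
        self.C = C
        self.scheme = scheme

    def fit(self, X, y):
        X = np.asarray(X, dtype=float).reshape(-1, 1)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 subtypes in the training set")
        if self.scheme == "ovo":
            self.model_ = SVC(kernel="linear", C=self.C)
            self.model_.fit(X, y)
        elif self.scheme == "ovr":
            self.model_ = OneVsRestClassifier(SVC(kernel="linear", C=self.C))
            self.model_.fit(X, y)
        elif self.scheme == "nearest_mean":
            self.means_ = {c: float(X[y == c, 0].mean()) for c in self.classes_}
        else:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float).reshape(-1, 1)
        if self.scheme in ("ovo", "ovr"):
            return self.model_.predict(X)
        order = sorted(self.means_)  # deterministic tie-break
        centres = np.array([self.means_[c] for c in order])
        idx = np.argmin(np.abs(X[:, 0][:, None] - centres[None, :]), axis=1)
        return np.array([order[i] for i in idx])

    def score(self, X, y) -> float:
        return float(np.mean(self.predict(X) == np.asarray(y)))

    def get_params(self, deep: bool = True) -> dict:
        return {"C": self.C, "scheme": self.scheme}

    def set_params(self, **params):
        for key, value in params.items():
            if key not in self.get_params():
                raise ValueError(f"unknown parameter {key!r}")
            setattr(self, key, value)
        return self


def _xy(records: Sequence[FDRecord], target: str) -> tuple[np.ndarray, np.ndarray]:
    X = np.array([[r.fd] for r in records])
    if target == "label":
        y = np.array([r.label for r in records])
    else:
        y = np.array([r.subtype for r in records])
    return X, y


def train_binary(train: Sequence[FDRecord], C: float = 1.0) -> FractalDimensionClassifier:
    """Fit the benign/malignant classifier on a record list."""
    X, y = _xy(train, "label")
    model = FractalDimensionClassifier(C=C).fit(X, y)
    model.n_train_ = len(train)
    return model


def evaluate_binary(
    model: FractalDimensionClassifier, test: Sequence[FDRecord]
) -> ClassificationReport:
    """Binary rates on a held-out record list.

    tp_rate = correctly-called-malignant / n_malignant, tn_rate likewise
    for benign; both classes must be present for the rates to exist.
    """
    if not test:
        raise ValueError("test set is empty")
    X, y = _xy(test, "label")
    if len(set(y.tolist())) < 2:
        raise ValueError("test set must contain both classes")
    pred = model.predict(X)
    is_mal = y == "malignant"
    tp = int(np.sum(is_mal & (pred == "malignant")))
    fn = int(np.sum(is_mal & (pred == "benign")))
    tn = int(np.sum(~is_mal & (pred == "benign")))
    fp = int(np.sum(~is_mal & (pred == "malignant")))
    tp_rate = tp / (tp + fn)
    tn_rate = tn / (tn + fp)
    return ClassificationReport(
        tp_rate=tp_rate,
        tn_rate=tn_rate,
        f1=harmonic_f1(tp_rate, tn_rate),
        accuracy=(tp + tn) / len(test),
        confusion={"tp": tp, "fn": fn, "tn": tn, "fp": fp},
        n_train=getattr(model, "n_train_", 0),
        n_test=len(test),
        threshold=model.threshold_,
    )


def train_multiclass(train: Sequence[FDRecord], C: float = 1.0, scheme: str = "ovo") -> SubtypeClassifier:
    X, y = _xy(train, "subtype")
    model = SubtypeClassifier(C=C, scheme=scheme).fit(X, y)
    model.n_train_ = len(train)
    return model


def evaluate_multiclass(
    model: SubtypeClassifier, test: Sequence[FDRecord]
) -> ClassificationReport:
    """Subtype accuracy plus an 8×8 confusion matrix.

    A subtype present in test but absent from training is counted as
    always wrong (the model cannot emit it) and triggers a warning.
    """
    if not test:
        raise ValueError("test set is empty")
    X, y = _xy(test, "subtype")
    unseen = sorted(set(y.tolist()) - set(model.classes_.tolist()))
    if unseen:
        warnings.warn(f"subtypes absent from training counted as wrong: {unseen}", stacklevel=2)
    pred = model.predict(X)
    correct = int(np.sum(pred == y))
    confusion = {
        true: {p: 0 for p in ALL_SUBTYPES} for true in ALL_SUBTYPES
    }
    for t, p in zip(y, pred):
        confusion[t][p] += 1
    # class-wise malignancy rates still defined via the subtype taxonomy
    true_mal = np.isin(y, MALIGNANT_SUBTYPES)
    pred_mal = np.isin(pred, MALIGNANT_SUBTYPES)
    tp_rate = float(np.mean(pred_mal[true_mal])) if true_mal.any() else 0.0
    tn_rate = float(np.mean(~pred_mal[~true_mal])) if (~true_mal).any() else 0.0
    return ClassificationReport(
        tp_rate=tp_rate,
        tn_rate=tn_rate,
        f1=harmonic_f1(tp_rate, tn_rate),
        accuracy=correct / len(test),
        confusion=confusion,
        n_train=getattr(model, "n_train_", 0),
        n_test=len(test),
    )


def cross_subtype_grid(
    records: Sequence[FDRecord], C: float = 1.0
) -> tuple[list[tuple[str, str, ClassificationReport]], float]:
    """The 16-combination generalization grid.

    For every (benign subtype, malignant subtype) pair, train a binary
    classifier on all records of those two subtypes only and evaluate it
    on all records of the remaining six subtypes.  Returns the 16
    per-pair reports and the arithmetic mean of their F1 scores.
    """
    present = {r.subtype for r in records}
    missing = sorted(set(ALL_SUBTYPES) - present)
    if missing:
        raise ValueError(f"missing subtypes: {missing}")
    results: list[tuple[str, str, ClassificationReport]] = []
    for bt in BENIGN_SUBTYPES:
        for mt in MALIGNANT_SUBTYPES:
            train = [r for r in records if r.subtype in (bt, mt)]
            test = [r for r in records if r.subtype not in (bt, mt)]
            model = train_binary(train, C=C)
            results.append((bt, mt, evaluate_binary(model, test)))
    mean_f1 = float(np.mean([rep.f1 for _, _, rep in results]))
    return results, mean_f1
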