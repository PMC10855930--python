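"""Linear maximum-margin classification of seeds on selected wavelengths.

The discrimination task is binary: legumes (the accept class, positive)
against gluten contaminants.  A linear support-vector classifier is
trained on standardized reflectance features at the selected wavelengths
with the protocol: 50% of objects for training, 25% for validation
(drives wavelength-selection stopping and the operating threshold), 25%
held out for a single final test; model stability is checked with
stratified 5-fold cross-validation inside the training portion.

Metric conventions follow the sorting application: TPR is the percentage
of legumes kept, FPR the percentage of contaminants wrongly kept, FNR the
percentage of legumes wrongly discarded, and the headline CCR equals the
legume-class rate (CCR = TPR = 100 - FNR).  Overall accuracy over both
classes is reported alongside.  Because a single admitted contaminant
ruins a gluten-free lot, the decision threshold can be shifted after
training to the operating point with zero false positives on validation
data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .containers import SpectrumTable, is_legume


class StratificationError(ValueError):
    """A class is too small to populate every split."""


@dataclass
class SplitSpec:
    """Stratified train/validation/test partition specification."""

    fractions: Tuple[float, float, float] = (0.50, 0.25, 0.25)
    stratified: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class ClassifierModel:
    """Linear decision rule over selected wavelengths.

    Features are standardized with the training mean/sd; a seed is
    accepted as legume when ``w . z + b > threshold``.
    """

    weights: np.ndarray
    bias: float
    mean: np.ndarray
    scale: np.ndarray
    selected_wavelengths: List[float]
    threshold: float = 0.0
    positive_class: str = "legume"

    def decision_values(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        z = (x - self.mean) / self.scale
        return z @ self.weights + self.bias

    def predict(self, x: np.ndarray) -> np.ndarray:
        """+1 accept (legume), -1 reject (contaminant)."""
        return np.where(self.decision_values(x) > self.threshold, 1, -1)

    def to_json(self, path) -> None:
        payload = {
            "selected_wavelengths": list(map(float, self.selected_wavelengths)),
            "weights": self.weights.tolist(),
            "bias": self.bias,
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "threshold": self.threshold,
            "positive_class": self.positive_class,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "ClassifierModel":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            weights=np.array(payload["weights"]),
            bias=float(payload["bias"]),
            mean=np.array(payload["mean"]),
            scale=np.array(payload["scale"]),
            selected_wavelengths=payload["selected_wavelengths"],
            threshold=float(payload["threshold"]),
            positive_class=payload.get("positive_class", "legume"),
        )


@dataclass
class EvalReport:
    """Confusion summary in the report-row shape: CCR, TPR, FPR, FNR (%)."""

    ccr: float
    tpr: float
    fpr: float
    fnr: float
    accuracy: float
    confusion: np.ndarray  # [[leg->leg, leg->cont], [cont->leg, cont->cont]]
    n_legumes: int
    n_contaminants: int
    dataset_name: str = ""
    wavelengths: List[float] = field(default_factory=list)

    def as_row(self) -> Dict[str, object]:
        return {
            "Dataset": self.dataset_name,
            "Wavelengths": "; ".join(f"{w:g}" for w in self.wavelengths),
            "CCR": round(self.ccr, 2),
            "TPR": round(self.tpr, 2),
            "FPR": round(self.fpr, 2),
            "FNR": round(self.fnr, 2),
        }


def split_data(
    table: SpectrumTable, spec: SplitSpec
) -> Tuple[SpectrumTable, SpectrumTable, SpectrumTable]:
    """Stratified, disjoint, exhaustive 50/25/25 partition of the table."""
    y = table.binary_labels()
    rng = np.random.default_rng(spec.rng_seed)
    parts: List[List[int]] = [[], [], []]
    groups = [np.flatnonzero(y == v) for v in (1, -1)] if spec.stratified \
        else [np.arange(len(table))]
    f1, f2, _ = spec.fractions
    for idx in groups:
        if spec.stratified and idx.size < 4:
            raise StratificationError(
                f"class with {idx.size} samples cannot populate three splits"
            )
        idx = idx[rng.permutation(idx.size)]
        c1 = int(round(f1 * idx.size))
        c2 = c1 + int(round(f2 * idx.size))
        parts[0] += idx[:c1].tolist()
        parts[1] += idx[c1:c2].tolist()
        parts[2] += idx[c2:].tolist()
    out = tuple(table.subset(np.sort(np.array(p, dtype=int))) for p in parts)
    for part in out:
        labels = set(part.binary_labels().tolist())
        if spec.stratified and labels != {1, -1}:
            raise StratificationError("a split lost one of the classes")
    return out


def train_linear(
    train: SpectrumTable,
    selected_wavelengths: Sequence[float],
    regularization: float = 1.0,
    rng_seed: int = 0,
    y: Optional[np.ndarray] = None,
) -> ClassifierModel:
    """Fit the linear SVM (hinge loss, L2 penalty) on standardized features.

    ``y`` overrides the table's own legume/contaminant labels with custom
    +1/-1 accept labels (used by the sorter, whose accept class is
    "cleanly exposed legume" rather than the botanical class).
    """
    if y is None:
        y = train.binary_labels()
    y = np.asarray(y)
    if len(set(y.tolist())) < 2:
        raise ValueError("training data must contain both classes")
    x = train.restrict(selected_wavelengths)
    mean = x.mean(axis=0)
    scale = x.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    z = (x - mean) / scale
    svc = SVC(kernel="linear", C=regularization, random_state=rng_seed)
    svc.fit(z, y)
    w = svc.coef_.ravel().copy()
    b = float(svc.intercept_[0])
    # ensure the positive decision side is the legume (+1) class
    if svc.classes_[1] != 1:
        w, b = -w, -b
    return ClassifierModel(
        weights=w,
        bias=b,
        mean=mean,
        scale=scale,
        selected_wavelengths=list(map(float, selected_wavelengths)),
    )


def shift_threshold_zero_fpr(
    model: ClassifierModel, validation: SpectrumTable, fnr_budget: float = 0.0,
    y: Optional[np.ndarray] = None,
) -> ClassifierModel:
    """Move the decision threshold to the zero-false-positive operating point.

    Every validation contaminant must fall below the threshold.  With
    ``fnr_budget`` zero the threshold bisects the empirical gap between the
    highest-scoring contaminant and the lowest-scoring legume above it.  A
    positive budget (fraction of legumes one is willing to discard, e.g. a
    little above the expected rate of badly exposed seeds) pushes the
    threshold up to the midpoint between the contaminant maximum and the
    legume score quantile at that budget: a degraded legume then no longer
    drags the operating point down into the ambiguous region, at the cost
    of a bounded extra legume loss.
    """
    d = model.decision_values(validation.restrict(model.selected_wavelengths))
    if y is None:
        y = validation.binary_labels()
    y = np.asarray(y)
    d_cont = d[y == -1]
    d_leg = d[y == 1]
    if d_cont.size == 0:
        raise ValueError("validation data contains no contaminants")
    top_cont = float(d_cont.max())
    ceiling = float(np.quantile(d_leg, fnr_budget)) if fnr_budget > 0 else -np.inf
    if ceiling > top_cont:
        t = 0.5 * (top_cont + ceiling)
    else:
        above = d_leg[d_leg > top_cont]
        t = 0.5 * (top_cont + float(above.min())) if above.size else top_cont + 1e-6
    model.threshold = max(model.threshold, t)
    return model


def confusion_metrics(
    predictions: Sequence, truth: Sequence, *, dataset_name: str = "",
    wavelengths: Sequence[float] = (), strict: bool = True,
) -> EvalReport:
    """CCR/TPR/FPR/FNR from predicted and true labels.

    Labels may be +1/-1 codes or class-name strings (mapped through the
    legume/contaminant vocabulary).  CCR follows the sorting convention:
    it is the legume-class rate, identical to TPR.  With ``strict`` off, a
    stream missing one class (an uncontaminated lot) is tolerated: the
    rate over the absent class is reported as 0.
    """

    def to_code(v):
        if isinstance(v, str):
            return 1 if is_legume(v) else -1
        if v in (1, -1):
            return int(v)
        raise ValueError(f"unknown label {v!r}")

    pred = np.array([to_code(v) for v in predictions])
    true = np.array([to_code(v) for v in truth])
    if pred.size != true.size:
        raise ValueError("prediction/truth length mismatch")
    tp = int(np.sum((true == 1) & (pred == 1)))
    fn = int(np.sum((true == 1) & (pred == -1)))
    fp = int(np.sum((true == -1) & (pred == 1)))
    tn = int(np.sum((true == -1) & (pred == -1)))
    n_leg, n_cont = tp + fn, fp + tn
    if strict and (n_leg == 0 or n_cont == 0):
        raise ValueError("both classes must appear in the truth labels")
    tpr = 100.0 * tp / n_leg if n_leg else 100.0
    fnr = 100.0 * fn / n_leg if n_leg else 0.0
    fpr = 100.0 * fp / n_cont if n_cont else 0.0
    return EvalReport(
        ccr=tpr,
        tpr=tpr,
        fpr=fpr,
        fnr=fnr,
        accuracy=100.0 * (tp + tn) / (n_leg + n_cont),
        confusion=np.array([[tp, fn], [fp, tn]]),
        n_legumes=n_leg,
        n_contaminants=n_cont,
        dataset_name=dataset_name,
        wavelengths=list(wavelengths),
    )


def evaluate(
    model: ClassifierModel, table: SpectrumTable, dataset_name: str = ""
) -> EvalReport:
    pred = model.predict(table.restrict(model.selected_wavelengths))
    return confusion_metrics(
        pred, table.binary_labels(), dataset_name=dataset_name,
        wavelengths=model.selected_wavelengths,
    )


def cross_validate(
    table: SpectrumTable,
    selected_wavelengths: Sequence[float],
    k: int = 5,
    rng_seed: int = 0,
    regularization: float = 1.0,
) -> Dict[str, object]:
    """Stratified k-fold cross-validation of the linear model; returns
    per-fold and aggregate CCR (legume-rate convention)."""
    from sklearn.model_selection import StratifiedKFold

    y = table.binary_labels()
    counts = min(int(np.sum(y == 1)), int(np.sum(y == -1)))
    if k > counts:
        raise ValueError(f"k={k} exceeds the smallest class count {counts}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rng_seed)
    fold_ccr = []
    for train_idx, test_idx in skf.split(table.spectra, y):
        model = train_linear(table.subset(train_idx), selected_wavelengths,
                             regularization=regularization, rng_seed=rng_seed)
        rep = evaluate(model, table.subset(test_idx))
        fold_ccr.append(rep.ccr)
    fold_ccr = np.array(fold_ccr)
    return {
        "fold_ccr": fold_ccr.tolist(),
        "mean_ccr": float(fold_ccr.mean()),
        "var_ccr": float(fold_ccr.var(ddof=1)) if k > 1 else 0.0,
        "k": k,
    }


def make_svm_wrapper(
    split: Optional[SplitSpec] = None,
    regularization: float = 1.0,
) -> Callable[[SpectrumTable, List[float]], float]:
    """Wrapper callback for forward selection: train on the 50% training
    portion, score on the validation split (never training data, so the
    stopping rule cannot trivially reach 100%).

    The score is the overall correct-classification percentage across both
    classes: scoring the legume rate alone would let a lopsidedly-thresholded
    model stop selection early by accepting everything.
    """
    split = split or SplitSpec()

    def wrapper(table: SpectrumTable, selected: List[float]) -> float:
        train, val, _ = split_data(table, split)
        model = train_linear(train, selected, regularization=regularization,
                             rng_seed=split.rng_seed)
        return evaluate(model, val).accuracy

    return wrapper


def default_classifier_families() -> Dict[str, Callable]:
    """Pluggable model families for the comparison harness (best-variant
    style survey; the linear SVM is the pipeline's own classifier)."""
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.naive_bayes import GaussianNB
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.neural_network import MLPClassifier
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.tree import DecisionTreeClassifier

    def scaled(est):
        return make_pipeline(StandardScaler(), est)

    return {
        "decision_tree": lambda seed: DecisionTreeClassifier(random_state=seed),
        "discriminant_analysis": lambda seed: LinearDiscriminantAnalysis(),
        "logistic_regression": lambda seed: scaled(LogisticRegression(max_iter=2000)),
        "naive_bayes": lambda seed: GaussianNB(),
        "svm_linear": lambda seed: scaled(SVC(kernel="linear", random_state=seed)),
        "nearest_neighbour": lambda seed: scaled(KNeighborsClassifier()),
        "ensemble": lambda seed: RandomForestClassifier(
            n_estimators=100, random_state=seed
        ),
        "neural_network": lambda seed: scaled(
            MLPClassifier(hidden_layer_sizes=(20,), max_iter=2000, random_state=seed)
        ),
    }


def compare_classifiers(
    table: SpectrumTable,
    selected_wavelengths: Sequence[float],
    families: Optional[Dict[str, Callable]] = None,
    split: Optional[SplitSpec] = None,
) -> pd.DataFrame:
    """Rank candidate classifier families by validation CCR.

    Returns one row per family with the legume-rate CCR and overall
    accuracy on the validation split; families that fail to train are
    recorded with NaN scores rather than aborting the comparison.
    """
    families = families or default_classifier_families()
    split = split or SplitSpec()
    train, val, _ = split_data(table, split)
    x_tr = train.restrict(selected_wavelengths)
    x_va = val.restrict(selected_wavelengths)
    y_tr = train.binary_labels()
    y_va = val.binary_labels()
    rows = []
    for name in sorted(families):
        try:
            est = families[name](split.rng_seed)
            est.fit(x_tr, y_tr)
            rep = confusion_metrics(est.predict(x_va), y_va, dataset_name=name)
            rows.append({"family": name, "ccr": rep.ccr, "accuracy": rep.accuracy,
                         "failed": False})
        except Exception:
            rows.append({"family": name, "ccr": np.nan, "accuracy": np.nan,
                         "failed": True})
    df = pd.DataFrame(rows).sort_values(
        by=["accuracy", "family"], ascending=[False, True], na_position="last"
    )
    return df.reset_index(drop=True)
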