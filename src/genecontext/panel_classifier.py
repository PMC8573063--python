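"""Panel-membership classification benchmark.

Each gene is labeled target (in the panel) or non-target and its TF-IDF
feature row is the input to seven classifier families: nearest neighbors,
linear SVM, Gaussian process, decision tree, random forest, neural net,
and Gaussian naive Bayes (scikit-learn, library defaults).  Evaluation is
stratified 5-fold cross-validation with metrics computed on the pooled
out-of-fold predictions: overall accuracy, per-class precision / recall /
F1, and a ROC curve with trapezoidal AUC built from each model's
continuous decision score (decision function where available, positive
class probability otherwise).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from sklearn.gaussian_process import GaussianProcessClassifier
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.ensemble import RandomForestClassifier

from genecontext.corpus_io import GenePanel
from genecontext.feature_matrix import GeneTermMatrix

MODEL_NAMES = (
    "nearest_neighbors",
    "linear_svm",
    "gaussian_process",
    "decision_tree",
    "random_forest",
    "neural_net",
    "naive_bayes",
)


def _make_model(name: str, seed: int):
    if name == "nearest_neighbors":
        return KNeighborsClassifier()
    if name == "linear_svm":
        return SVC(kernel="linear")
    if name == "gaussian_process":
        return GaussianProcessClassifier(random_state=seed)
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if name == "random_forest":
        return RandomForestClassifier(random_state=seed)
    if name == "neural_net":
        return MLPClassifier(random_state=seed, max_iter=1000)
    if name == "naive_bayes":
        return GaussianNB()
    raise ValueError(f"unknown model spec {name!r}; choose from {MODEL_NAMES}")


@dataclass
class ClassifierReport:
    """Pooled out-of-fold CV results for one model."""

    model: str
    folds: int
    seed: int
    accuracy: float
    precision: dict[str, float]  # per class: "target" / "non_target"
    recall: dict[str, float]
    f1: dict[str, float]
    fold_assignments: list[int]
    roc_fpr: list[float]
    roc_tpr: list[float]
    auc: float

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload, encoding="utf-8")
        return payload

    @classmethod
    def from_json(cls, payload: str | Path) -> "ClassifierReport":
        if isinstance(payload, Path) or (
            isinstance(payload, str) and "\n" not in payload and Path(payload).exists()
        ):
            payload = Path(payload).read_text(encoding="utf-8")
        return cls(**json.loads(payload))


def make_labels(matrix: GeneTermMatrix, panel: GenePanel) -> np.ndarray:
    """Binary vector over matrix genes: 1 iff the gene is in the panel."""
    y = np.array([1 if g in panel else 0 for g in matrix.genes], dtype=int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError(
            f"degenerate labeling: {int(y.sum())} targets of {len(y)} genes"
        )
    return y


def roc_auc(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC by threshold sweep over unique scores; AUC by trapezoid.

    Returns (fpr, tpr, auc); the curve starts at (0, 0) and ends at (1, 1).
    Invariant under strictly increasing transforms of the scores.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y)
    if not np.isfinite(scores).all():
        raise ValueError("non-finite decision scores")
    pos, neg = int((y == 1).sum()), int((y == 0).sum())
    if pos == 0 or neg == 0:
        raise ValueError("ROC requires both classes present")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    tps = np.cumsum(y[order] == 1)
    fps = np.cumsum(y[order] == 0)
    # keep only the last index of each tied score block
    distinct = np.r_[np.flatnonzero(np.diff(sorted_scores)), len(scores) - 1]
    tpr = np.r_[0.0, tps[distinct] / pos]
    fpr = np.r_[0.0, fps[distinct] / neg]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def cross_validate(
    X: np.ndarray | sp.spmatrix | GeneTermMatrix,
    y: np.ndarray,
    model_spec: str,
    folds: int = 5,
    seed: int = 0,
) -> ClassifierReport:
    """Stratified K-fold CV with pooled out-of-fold metrics.

    Every sample is predicted exactly once, by the model trained on the
    other folds; accuracy, per-class precision/recall/F1, ROC and AUC are
    computed on that pooled vector.  Deterministic given the seed.
    """
    if isinstance(X, GeneTermMatrix):
        mat = X.scores if X.scores is not None else X.counts
        X = np.asarray(mat.todense(), dtype=float)
    elif sp.issparse(X):
        X = np.asarray(X.todense(), dtype=float)
    else:
        X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if model_spec not in MODEL_NAMES:
        raise ValueError(f"unknown model spec {model_spec!r}; choose from {MODEL_NAMES}")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = np.empty_like(y)
    score = np.empty(len(y), dtype=float)
    fold_of = np.empty(len(y), dtype=int)
    for fold, (train, test) in enumerate(skf.split(X, y)):
        model = _make_model(model_spec, seed)
        model.fit(X[train], y[train])
        pred[test] = model.predict(X[test])
        if hasattr(model, "decision_function"):
            score[test] = model.decision_function(X[test])
        else:
            score[test] = model.predict_proba(X[test])[:, 1]
        fold_of[test] = fold

    accuracy = float((pred == y).mean())
    prec, rec, f1, _ = precision_recall_fscore_support(
        y, pred, labels=[1, 0], zero_division=0
    )
    fpr, tpr, auc = roc_auc(score, y)
    return ClassifierReport(
        model=model_spec,
        folds=folds,
        seed=seed,
        accuracy=accuracy,
        precision={"target": float(prec[0]), "non_target": float(prec[1])},
        recall={"target": float(rec[0]), "non_target": float(rec[1])},
        f1={"target": float(f1[0]), "non_target": float(f1[1])},
        fold_assignments=[int(f) for f in fold_of],
        roc_fpr=[float(v) for v in fpr],
        roc_tpr=[float(v) for v in tpr],
        auc=auc,
    )


def benchmark_models(
    X, y, models=MODEL_NAMES, folds: int = 5, seed: int = 0
) -> dict[str, ClassifierReport]:
    """Run :func:`cross_validate` for each requested model family."""
    return {m: cross_validate(X, y, m, folds=folds, seed=seed) for m in models}
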