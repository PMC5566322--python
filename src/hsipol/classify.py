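"""Two-class linear discriminant analysis with stratified 10-fold
cross-validation and fold-summed confusion matrices.

Classic LDA with equal priors and a shared (pooled) within-class
covariance, as appropriate for the balanced 30 + 30 design of the study.
A small ridge on the covariance diagonal (default 1e-6 x its mean
diagonal) guards against near-collinear smooth spectral bands.  The
cross-validation mirrors the study's protocol: stratified 10 folds,
confusion matrices and errors computed from the summation over the 10
test sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .core import CLASS_LABELS


@dataclass(frozen=True)
class LDAModel:
    """Fitted two-class LDA in the selected-band space.

    ``weight_vector = (pooled_covariance + ridge I)^-1 (mean_M1 - mean_M2)``
    and ``threshold = weight . (mean_M1 + mean_M2) / 2`` (equal priors).
    ``degenerate`` flags identical class means (zero weight vector).
    """

    class_means: dict
    pooled_covariance: np.ndarray
    ridge: float
    weight_vector: np.ndarray
    threshold: float
    degenerate: bool = False


@dataclass(frozen=True)
class CVResult:
    """Fold-summed cross-validation outcome.

    ``confusion`` is a 2x2 integer matrix, rows = true class (M1, M2),
    columns = predicted, summed over the k test folds; its total equals
    the number of observations.  ``accuracy`` = trace / total.
    """

    confusion: np.ndarray
    accuracy: float
    error: float
    fold_count: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "confusion": [[int(v) for v in row] for row in self.confusion],
            "accuracy": self.accuracy,
            "error": self.error,
            "k": self.fold_count,
            "seed": self.seed,
        }

    def format_confusion(self) -> str:
        """Plain-text confusion table (rows true, columns predicted)."""
        c = self.confusion
        lines = ["            pred M1   pred M2",
                 f"true M1  {c[0, 0]:8d}  {c[0, 1]:8d}",
                 f"true M2  {c[1, 0]:8d}  {c[1, 1]:8d}",
                 f"accuracy {self.accuracy:.4f}  (k={self.fold_count})"]
        return "\n".join(lines)


def _split_classes(X: np.ndarray, labels) -> dict[str, np.ndarray]:
    labels = np.asarray(labels, dtype=object)
    out = {}
    for cls in CLASS_LABELS:
        out[cls] = X[labels == cls]
    return out


def fit_lda(X, labels, ridge: float | None = None) -> LDAModel:
    """Fit two-class LDA from class means and pooled covariance.

    ``ridge`` defaults to ``1e-6 x mean diagonal`` of the pooled
    covariance.  Both classes need at least 2 observations.  Raises with
    advice to increase the ridge if the stabilized covariance is still
    singular.
    """
    X = np.asarray(X, dtype=float)
    groups = _split_classes(X, labels)
    for cls, Xc in groups.items():
        if Xc.shape[0] < 2:
            raise ValueError(f"class {cls} needs at least 2 observations")
    n = X.shape[0]
    means = {cls: Xc.mean(axis=0) for cls, Xc in groups.items()}
    scatter = sum(
        (Xc - means[cls]).T @ (Xc - means[cls]) for cls, Xc in groups.items()
    )
    pooled = scatter / (n - 2)
    if ridge is None:
        ridge = 1e-6 * float(np.mean(np.diag(pooled)))
    delta = means["M1"] - means["M2"]
    degenerate = bool(np.allclose(delta, 0.0))
    stabilized = pooled + ridge * np.eye(pooled.shape[0])
    try:
        w = linalg.solve(stabilized, delta, assume_a="pos")
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"pooled covariance + ridge*I is singular (ridge={ridge:g}); "
            "increase the ridge") from exc
    threshold = float(w @ (means["M1"] + means["M2"]) / 2.0)
    return LDAModel(class_means=means, pooled_covariance=pooled, ridge=float(ridge),
                    weight_vector=w, threshold=threshold, degenerate=degenerate)


def predict_lda(model: LDAModel, X) -> np.ndarray:
    """Predict M1 where ``weight . x > threshold``, M2 otherwise (exact
    ties go to M2 by convention)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.weight_vector.size:
        raise ValueError(
            f"X must be 2-D with {model.weight_vector.size} features")
    scores = X @ model.weight_vector
    return np.where(scores > model.threshold, "M1", "M2").astype(object)


def stratified_kfold(labels, k: int = 10, seed: int = 0) -> list[np.ndarray]:
    """Seeded stratified k-fold split: test-index arrays whose per-class
    counts differ by at most one across folds.

    Each class is shuffled and dealt round-robin, so the folds partition
    all indices.  A class smaller than ``k`` is rejected.
    """
    labels = np.asarray(labels, dtype=object)
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in CLASS_LABELS:
        idx = np.flatnonzero(labels == cls)
        if idx.size < k:
            raise ValueError(f"class {cls} has {idx.size} < k={k} observations")
        idx = rng.permutation(idx)
        for pos, i in enumerate(idx):
            folds[pos % k].append(int(i))
    return [np.sort(np.array(f, dtype=int)) for f in folds]


def cross_validate(X, labels, k: int = 10, seed: int = 0,
                   ridge: float | None = None) -> CVResult:
    """Stratified k-fold CV with fold-summed confusion counts.

    For each fold the model is fitted on the remaining k-1 folds and
    evaluated on the held-out fold; the 2x2 confusion counts are
    accumulated over folds and the accuracy computed from the summed
    matrix.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels, dtype=object)
    folds = stratified_kfold(labels, k=k, seed=seed)
    confusion = np.zeros((2, 2), dtype=int)
    cls_index = {cls: i for i, cls in enumerate(CLASS_LABELS)}
    for test_idx in folds:
        train_mask = np.ones(X.shape[0], dtype=bool)
        train_mask[test_idx] = False
        model = fit_lda(X[train_mask], labels[train_mask], ridge=ridge)
        predicted = predict_lda(model, X[test_idx])
        for true, pred in zip(labels[test_idx], predicted):
            confusion[cls_index[true], cls_index[pred]] += 1
    total = int(confusion.sum())
    accuracy = float(np.trace(confusion)) / total
    return CVResult(confusion=confusion, accuracy=accuracy, error=1.0 - accuracy,
                    fold_count=k, seed=seed)
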