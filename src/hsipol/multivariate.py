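"""PCA of spectra tables, separating-component identification, half-plane
classification and loading-guided wavelength selection.

The study performed covariance PCA on the raw (mean-centered, unscaled)
reflectance intensities at 26 wavelengths, identified by eye the
principal component along which M1 and M2 separate (PC2 in its data,
explaining 8-22% of the variance), classified cells by the sign of their
score on that component (~10% mean error), and picked 14 wavelengths
with large loading magnitude as LDA predictors.  This module automates
the two visual steps with deterministic rules: the separating component
maximizes the absolute two-sample t statistic of its scores over the
first few candidates, and bands are the top-k loadings by magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import CLASS_LABELS, SpectraTable

#: |t| below this flags the separating axis as low-confidence
LOW_CONFIDENCE_T = 2.0


@dataclass(frozen=True)
class PCAModel:
    """Principal components of a spectra table.

    ``loadings`` is components x wavelengths with orthonormal rows;
    ``scores`` is observations x components; ``explained_variance`` holds
    the per-component score variances (descending, denominator n-1).
    Component signs follow the convention that each loading's
    largest-magnitude coefficient is positive, so results are seed-stable.
    """

    mean_spectrum: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    explained_variance: np.ndarray
    wavelengths: np.ndarray

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    def explained_fractions(self) -> np.ndarray:
        total = self.explained_variance.sum()
        if total <= 0:
            raise ValueError("total variance is zero; fractions undefined")
        return self.explained_variance / total


@dataclass(frozen=True)
class SeparatingAxis:
    """The oriented principal component that separates the two classes.

    ``component_index`` is 1-based (PC1 = 1).  ``orientation`` is +1 or
    -1 chosen so the M1 class has positive mean score.  ``low_confidence``
    is set when |t| < 2, i.e. the separation is not distinguishable from
    chance.
    """

    component_index: int
    orientation: int
    t_statistic: float

    @property
    def low_confidence(self) -> bool:
        return bool(abs(self.t_statistic) < LOW_CONFIDENCE_T)


def fit_pca(table: SpectraTable) -> PCAModel:
    """Covariance PCA via SVD of the mean-centered intensity matrix.

    No variance scaling: bands share units, and the analysis operates on
    raw reflectance.  Requires at least 2 observations and 2 wavelengths.
    """
    X = table.intensities
    n, m = X.shape
    if n < 2 or m < 2:
        raise ValueError("PCA needs at least 2 observations and 2 wavelengths")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    # sign convention: largest-|coefficient| loading entry positive
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    scores = Xc @ Vt.T
    explained = (s ** 2) / (n - 1)
    return PCAModel(mean_spectrum=mean, loadings=Vt, scores=scores,
                    explained_variance=explained, wavelengths=table.wavelengths)


def explained_fraction(model: PCAModel, j: int) -> float:
    """Fraction of total variance carried by component ``j`` (1-based)."""
    if not (1 <= j <= model.n_components):
        raise ValueError(f"component index {j} out of range 1..{model.n_components}")
    return float(model.explained_fractions()[j - 1])


def find_separating_pc(model: PCAModel, labels, n_candidates: int = 5) -> SeparatingAxis:
    """Choose the component separating M1 from M2.

    Among the first ``n_candidates`` components, picks the one with the
    largest |two-sample t| of scores between classes (ties toward the
    lower index), oriented so the M1 mean score is positive.
    """
    labels = np.asarray(labels, dtype=object)
    m1, m2 = labels == "M1", labels == "M2"
    if not (m1.any() and m2.any()):
        raise ValueError("both classes must be present to find a separating axis")
    n_candidates = min(n_candidates, model.n_components)
    if n_candidates < 1:
        raise ValueError("n_candidates must be >= 1")
    t_stats = np.empty(n_candidates)
    for j in range(n_candidates):
        t, _ = stats.ttest_ind(model.scores[m1, j], model.scores[m2, j],
                               equal_var=True)
        t_stats[j] = float(t) if np.isfinite(t) else 0.0
    best_j = int(np.argmax(np.abs(t_stats)))  # argmax ties go to the lower index
    orientation = 1 if model.scores[m1, best_j].mean() >= model.scores[m2, best_j].mean() else -1
    return SeparatingAxis(component_index=best_j + 1, orientation=orientation,
                          t_statistic=t_stats[best_j])


def halfplane_classify(axis: SeparatingAxis, model: PCAModel, labels) -> float:
    """Error rate of the sign-of-score classifier on the separating axis.

    Predicts M1 where ``orientation * score > 0`` and M2 otherwise
    (a score of exactly 0 is classified M2 by convention).
    """
    labels = np.asarray(labels, dtype=object)
    s = axis.orientation * model.scores[:, axis.component_index - 1]
    predicted = np.where(s > 0, "M1", "M2")
    return float(np.mean(predicted != labels))


def select_bands(model: PCAModel, axis: SeparatingAxis, n_select: int = 14,
                 min_spacing_nm: float | None = None) -> np.ndarray:
    """The ``n_select`` wavelengths with largest |loading| on the
    separating component, returned sorted ascending.

    Ties break toward the lower wavelength.  ``min_spacing_nm`` optionally
    enforces a minimum gap between selected bands (greedy, in loading
    order); default off.
    """
    if n_select <= 0:
        raise ValueError("n_select must be positive")
    loading = model.loadings[axis.component_index - 1]
    if n_select > loading.size:
        raise ValueError(f"cannot select {n_select} of {loading.size} wavelengths")
    # lexsort: primary key last -> descending |loading|, then ascending wavelength
    order = np.lexsort((model.wavelengths, -np.abs(loading)))
    if min_spacing_nm is None:
        chosen = order[:n_select]
    else:
        chosen = []
        for idx in order:
            if all(abs(model.wavelengths[idx] - model.wavelengths[c]) >= min_spacing_nm
                   for c in chosen):
                chosen.append(idx)
            if len(chosen) == n_select:
                break
        if len(chosen) < n_select:
            raise ValueError("min_spacing_nm too large for the requested n_select")
        chosen = np.array(chosen)
    return np.sort(model.wavelengths[chosen])
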