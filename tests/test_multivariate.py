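"""PCA, separating component, half-plane classifier, band selection."""

import numpy as np
import pytest

from hsipol.core import SpectraTable, default_geometry
from hsipol.extract import preprocess_table
from hsipol.multivariate import (PCAModel, SeparatingAxis, explained_fraction,
                                 find_separating_pc, fit_pca,
                                 halfplane_classify, select_bands)
from hsipol.pipeline import DEFAULT_MODEL, derive_seeds
from hsipol.synth import make_cohort

WL26 = np.linspace(500, 1000, 26)


def _table(X, labels=None, donors=None, wl=None):
    n = X.shape[0]
    labels = labels if labels is not None else ["M1"] * (n // 2) + ["M2"] * (n - n // 2)
    return SpectraTable(wl if wl is not None else np.arange(X.shape[1], dtype=float) + 500.0,
                        X, labels, donors if donors is not None else ["D1"] * n)


class TestFitPCA:
    def test_identical_rows_have_zero_variance(self):
        table = _table(np.tile([1.0, 2.0, 3.0], (6, 1)))
        model = fit_pca(table)
        np.testing.assert_allclose(model.explained_variance, 0.0, atol=1e-20)

    def test_leading_component_matches_analytic_2x2_eigenvector(self, rng):
        # closed-form eigendecomposition of a 2x2 covariance as oracle
        cov = np.array([[2.0, 0.8], [0.8, 1.0]])
        L = np.linalg.cholesky(cov)
        X = rng.standard_normal((4000, 2)) @ L.T
        model = fit_pca(_table(X))
        tr, det = cov.trace(), np.linalg.det(cov)
        lam1 = tr / 2 + np.sqrt(tr ** 2 / 4 - det)
        v1 = np.array([cov[0, 1], lam1 - cov[0, 0]])
        v1 /= np.linalg.norm(v1)
        dot = abs(model.loadings[0] @ v1)
        assert dot > 0.999

    def test_fractions_sum_to_one(self, rng):
        model = fit_pca(_table(rng.uniform(0, 1, (20, 8))))
        assert model.explained_fractions().sum() == pytest.approx(1.0, abs=1e-9)

    def test_loadings_orthonormal_and_reconstruction_exact(self, rng):
        X = rng.uniform(0, 1, (15, 6))
        model = fit_pca(_table(X))
        gram = model.loadings @ model.loadings.T
        np.testing.assert_allclose(gram, np.eye(gram.shape[0]), atol=1e-8)
        recon = model.mean_spectrum + model.scores @ model.loadings
        np.testing.assert_allclose(recon, X, atol=1e-8)

    def test_sign_convention_largest_coefficient_positive(self, rng):
        model = fit_pca(_table(rng.uniform(0, 1, (30, 7))))
        for loading in model.loadings:
            assert loading[np.argmax(np.abs(loading))] > 0

    def test_matches_eigendecomposition_oracle(self, rng):
        # independent route: eigh of the sample covariance matrix
        X = rng.uniform(0, 1, (20, 26))
        model = fit_pca(_table(X, wl=WL26))
        cov = np.cov(X, rowvar=False)
        evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        k = model.explained_variance.size
        np.testing.assert_allclose(model.explained_variance, evals[:k],
                                   rtol=1e-6, atol=1e-12)

    def test_matches_sklearn_cross_check(self, rng):
        sklearn_pca = pytest.importorskip("sklearn.decomposition").PCA
        X = rng.uniform(0, 1, (25, 10))
        model = fit_pca(_table(X))
        sk = sklearn_pca().fit(X)
        np.testing.assert_allclose(model.explained_variance,
                                   sk.explained_variance_[:model.n_components],
                                   rtol=1e-8)
        for ours, theirs in zip(model.loadings, sk.components_):
            assert abs(ours @ theirs) == pytest.approx(1.0, abs=1e-8)

    def test_single_row_rejected(self):
        with pytest.raises(ValueError):
            fit_pca(_table(np.ones((1, 4)), labels=["M1"], donors=["D1"]))


class TestExplainedFraction:
    def test_rank_one_data(self):
        direction = np.array([1.0, 2.0, 2.0])
        X = np.outer(np.arange(8, dtype=float), direction)
        model = fit_pca(_table(X))
        assert explained_fraction(model, 1) == pytest.approx(1.0, abs=1e-9)
        assert explained_fraction(model, 2) == pytest.approx(0.0, abs=1e-9)

    def test_fractions_partition_unity(self, rng):
        model = fit_pca(_table(rng.uniform(0, 1, (12, 5))))
        total = sum(explained_fraction(model, j + 1)
                    for j in range(model.n_components))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_zero_variance_rejected(self):
        model = fit_pca(_table(np.ones((4, 3))))
        with pytest.raises(ValueError, match="zero"):
            explained_fraction(model, 1)


def _counter_dominance_table(rng, n=200):
    """Max-variance direction carries no class signal; the class mean
    difference lies along the second variance direction."""
    labels = np.array(["M1"] * n + ["M2"] * n, dtype=object)
    sign = np.where(labels == "M1", 1.0, -1.0)
    x1 = rng.normal(0, 3.0, 2 * n)            # dominant, non-discriminative
    x2 = sign * 1.0 + rng.normal(0, 0.3, 2 * n)  # minor, discriminative
    x3 = rng.normal(0, 0.1, 2 * n)
    X = np.column_stack([x1, x2, x3])
    return _table(X, labels=list(labels))


class TestFindSeparatingPC:
    def test_counter_dominance_returns_second_component(self, rng):
        table = _counter_dominance_table(rng)
        model = fit_pca(table)
        axis = find_separating_pc(model, table.labels, n_candidates=3)
        assert axis.component_index == 2
        assert not axis.low_confidence

    def test_shuffled_labels_flag_low_confidence(self, rng):
        table = _counter_dominance_table(rng)
        labels = rng.permutation(np.asarray(table.labels))
        model = fit_pca(table)
        axis = find_separating_pc(model, labels, n_candidates=3)
        assert abs(axis.t_statistic) < 4  # no structure to find
        # with enough shuffles most are below 2; check the flag wiring
        assert axis.low_confidence == (abs(axis.t_statistic) < 2)

    def test_label_swap_flips_orientation_keeps_t_magnitude(self, rng):
        table = _counter_dominance_table(rng)
        model = fit_pca(table)
        axis = find_separating_pc(model, table.labels, n_candidates=3)
        swapped = np.where(np.asarray(table.labels) == "M1", "M2", "M1")
        axis2 = find_separating_pc(model, swapped, n_candidates=3)
        assert axis2.orientation == -axis.orientation
        assert abs(axis2.t_statistic) == pytest.approx(abs(axis.t_statistic))

    def test_m1_mean_score_positive_after_orientation(self, rng):
        table = _counter_dominance_table(rng)
        model = fit_pca(table)
        axis = find_separating_pc(model, table.labels, n_candidates=3)
        scores = axis.orientation * model.scores[:, axis.component_index - 1]
        assert scores[np.asarray(table.labels) == "M1"].mean() >= \
            scores[np.asarray(table.labels) == "M2"].mean()

    def test_single_class_rejected(self, rng):
        table = _table(rng.uniform(0, 1, (8, 4)), labels=["M1"] * 8)
        model = fit_pca(table)
        with pytest.raises(ValueError, match="both classes"):
            find_separating_pc(model, table.labels)


def _toy_axis_model(scores_1d, wl=None):
    """PCAModel carrying one explicit score column for half-plane tests."""
    scores = np.asarray(scores_1d, dtype=float)[:, None]
    m = 4 if wl is None else wl.size
    return PCAModel(mean_spectrum=np.zeros(m),
                    loadings=np.zeros((1, m)),
                    scores=scores,
                    explained_variance=np.array([scores.var()]),
                    wavelengths=wl if wl is not None else np.arange(m, dtype=float))


class TestHalfplaneClassify:
    def test_perfectly_signed_scores_zero_error(self):
        model = _toy_axis_model([2.0, 1.0, -1.0, -2.0])
        axis = SeparatingAxis(1, 1, 10.0)
        assert halfplane_classify(axis, model, ["M1", "M1", "M2", "M2"]) == 0.0

    def test_orientation_flip_complements_error(self):
        scores = [2.0, 1.0, -0.5, -2.0, -1.0, 0.5]
        labels = ["M1", "M1", "M1", "M2", "M2", "M2"]
        model = _toy_axis_model(scores)
        e = halfplane_classify(SeparatingAxis(1, 1, 5.0), model, labels)
        e_flip = halfplane_classify(SeparatingAxis(1, -1, 5.0), model, labels)
        assert e_flip == pytest.approx(1.0 - e)

    def test_enumerated_toy_error_two_sixths(self):
        # hand count: M1 at -0.5 wrong, M2 at +0.5 wrong -> 2/6
        scores = [2.0, 1.0, -0.5, -2.0, -1.0, 0.5]
        labels = ["M1", "M1", "M1", "M2", "M2", "M2"]
        model = _toy_axis_model(scores)
        e = halfplane_classify(SeparatingAxis(1, 1, 5.0), model, labels)
        assert e == pytest.approx(2 / 6)

    def test_zero_score_classified_m2(self):
        model = _toy_axis_model([0.0])
        assert halfplane_classify(SeparatingAxis(1, 1, 1.0), model, ["M2"]) == 0.0
        assert halfplane_classify(SeparatingAxis(1, 1, 1.0), model, ["M1"]) == 1.0


class TestSelectBands:
    def test_study_defaults_select_14_of_26(self, native_cohort):
        table = preprocess_table(native_cohort)
        model = fit_pca(table)
        axis = find_separating_pc(model, table.labels)
        bands = select_bands(model, axis, 14)
        assert bands.size == 14
        assert np.all(np.diff(bands) > 0)
        assert set(bands) <= set(WL26)

    def test_selecting_all_returns_whole_grid(self, native_cohort):
        table = preprocess_table(native_cohort)
        model = fit_pca(table)
        axis = find_separating_pc(model, table.labels)
        np.testing.assert_array_equal(select_bands(model, axis, 26), WL26)

    def test_hand_ranked_loadings(self):
        wl = np.array([500.0, 520.0, 540.0, 560.0])
        model = PCAModel(mean_spectrum=np.zeros(4),
                         loadings=np.array([[0.9, -0.8, 0.1, 0.05]]),
                         scores=np.zeros((2, 1)),
                         explained_variance=np.array([1.0]),
                         wavelengths=wl)
        axis = SeparatingAxis(1, 1, 3.0)
        np.testing.assert_array_equal(select_bands(model, axis, 2),
                                      [500.0, 520.0])

    def test_ties_break_toward_lower_wavelength(self):
        wl = np.array([500.0, 520.0, 540.0])
        model = PCAModel(mean_spectrum=np.zeros(3),
                         loadings=np.array([[0.5, -0.5, 0.5]]),
                         scores=np.zeros((2, 1)),
                         explained_variance=np.array([1.0]),
                         wavelengths=wl)
        np.testing.assert_array_equal(
            select_bands(model, SeparatingAxis(1, 1, 3.0), 2), [500.0, 520.0])

    def test_nonpositive_count_rejected(self, native_cohort):
        table = preprocess_table(native_cohort)
        model = fit_pca(table)
        axis = find_separating_pc(model, table.labels)
        with pytest.raises(ValueError):
            select_bands(model, axis, 0)


class TestProperties:
    def test_scale_equivariance(self, native_cohort):
        table = preprocess_table(native_cohort)
        c = 3.7
        scaled = SpectraTable(table.wavelengths, c * table.intensities,
                              table.labels, table.donors)
        m1, m2 = fit_pca(table), fit_pca(scaled)
        np.testing.assert_allclose(m2.explained_variance,
                                   c ** 2 * m1.explained_variance, rtol=1e-9)
        np.testing.assert_allclose(m2.explained_fractions(),
                                   m1.explained_fractions(), rtol=1e-9)
        a1 = find_separating_pc(m1, table.labels)
        a2 = find_separating_pc(m2, table.labels)
        assert a1.component_index == a2.component_index
        np.testing.assert_array_equal(select_bands(m1, a1, 14),
                                      select_bands(m2, a2, 14))

    def test_band_recovery_of_planted_class_effect(self, geometry):
        """select_bands recovers >= 80% of the grid wavelengths within one
        grid step of a planted effect center, averaged over 20 seeds."""
        centers = [f.center_nm for f in DEFAULT_MODEL.class_effect]
        targets = {w for w in WL26 if any(abs(w - c) <= 20.0 for c in centers)}
        recovered = []
        for seed in derive_seeds(7, 20):
            table = preprocess_table(
                make_cohort(DEFAULT_MODEL, 1, 30, geometry.wavelengths, seed))
            model = fit_pca(table)
            axis = find_separating_pc(model, table.labels)
            sel = set(select_bands(model, axis, 14))
            recovered.append(len(sel & targets) / len(targets))
        assert np.mean(recovered) >= 0.8
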