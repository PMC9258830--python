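import numpy as np
import pytest

from cbgt.ddm import DDMParams, mean_rt_ddm
from cbgt.ensemble import (
    ControlEnsembleAnalysis, FeatureMatrices, canonical_loadings, cca_fit,
    cca_score, cross_validate_cca, kmeans_with_silhouette,
    regression_influence, sensitivity_normalize, silhouette_brute_force,
)
from cbgt.surrogate import SurrogateSpec, generate_wrp


class TestRegressionInfluence:
    def test_self_regression_slope_one_zero_width(self, rng):
        x = rng.standard_normal((50, 1))
        df = regression_influence(x, x.copy())
        assert df.loc[0, "slope"] == pytest.approx(1.0)
        assert df.loc[0, "se"] == pytest.approx(0.0, abs=1e-10)

    def test_planted_slope_recovered(self, rng):
        n = 2000
        x = rng.standard_normal((n, 1))
        z = (x - x.mean()) / x.std(ddof=1)
        y = 0.5 * z + np.sqrt(0.75) * rng.standard_normal((n, 1))
        df = regression_influence(x, y)
        assert df.loc[0, "slope"] == pytest.approx(0.5, abs=0.06)

    def test_interval_coverage_under_independence(self, rng):
        """95% CI covers zero for independent pairs at nominal rate."""
        covered = 0
        reps = 800
        for _ in range(reps):
            x = rng.standard_normal((40, 1))
            y = rng.standard_normal((40, 1))
            covered += bool(regression_influence(x, y).loc[0, "covers_zero"])
        assert covered / reps >= 0.93

    def test_zero_variance_rejected(self, rng):
        x = np.ones((20, 1))
        with pytest.raises(ValueError):
            regression_influence(x, rng.standard_normal((20, 1)))


class TestCCA:
    def test_permuted_copy_gives_unit_correlation(self, rng):
        X = rng.standard_normal((120, 5))
        Y = X[:, [4, 2, 0, 1, 3]]
        m = cca_fit(X, Y, 3)
        assert m.canonical_correlations[0] == pytest.approx(1.0, abs=1e-8)

    def test_planted_latent_recovered(self):
        vals = [cca_fit(*(lambda d: (d.W, d.R))(
                    generate_wrp(SurrogateSpec(n_samples=300, rho_wr=(0.9,),
                                               rho_rp=(0.9,), seed=k))), 1
                        ).canonical_correlations[0]
                for k in range(20)]
        assert np.mean(vals) == pytest.approx(0.9, abs=0.07)

    def test_independent_blocks_score_near_zero_held_out(self, rng):
        X = rng.standard_normal((200, 8))
        Y = rng.standard_normal((200, 6))
        m = cca_fit(X[:150], Y[:150], 2)
        assert m.canonical_correlations[0] > 0.1      # training optimism
        assert cca_score(m, X[150:], Y[150:]) < 0.1   # no generalization

    def test_component_count_cap(self, rng):
        with pytest.raises(ValueError):
            cca_fit(rng.standard_normal((30, 3)), rng.standard_normal((30, 2)), 3)

    def test_affine_rescaling_invariance(self, rng):
        X = rng.standard_normal((100, 4))
        Y = 0.5 * X[:, :3] + 0.3 * rng.standard_normal((100, 3))
        c1 = cca_fit(X, Y, 2).canonical_correlations
        c2 = cca_fit(X * [2.0, 0.1, 5.0, 1.0] + 3.0, Y * 10.0 - 1.0, 2
                     ).canonical_correlations
        assert np.allclose(c1, c2, atol=1e-6)


class TestScore:
    class StubModel:
        def __init__(self, pred):
            self.pred = pred

        def predict(self, X):
            return self.pred

    def test_perfect_prediction_scores_one(self, rng):
        Y = rng.standard_normal((10, 3))
        assert cca_score(self.StubModel(Y.copy()), None, Y) == pytest.approx(1.0)

    def test_grand_mean_prediction_scores_zero(self, rng):
        Y = rng.standard_normal((10, 3))
        pred = np.full_like(Y, Y.mean())
        assert cca_score(self.StubModel(pred), None, Y) == pytest.approx(0.0)

    def test_hand_computed_toy(self):
        Y = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        pred = np.array([[1.0, 2.0], [3.0, 5.0], [4.0, 6.0]])
        a = 0.0 + 1.0 + 1.0
        b = np.sum((Y - Y.mean()) ** 2)
        assert cca_score(self.StubModel(pred), None, Y) == pytest.approx(1 - a / b)

    def test_constant_target_rejected(self):
        with pytest.raises(ValueError):
            cca_score(self.StubModel(np.ones((5, 2))), None, np.ones((5, 2)))


class TestCrossValidation:
    def test_surrogate_selects_planted_dimension(self):
        d = generate_wrp(SurrogateSpec(n_samples=300, rho_wr=(0.9, 0.8),
                                       rho_rp=(0.9,), seed=5))
        cv = cross_validate_cca(d.W, d.R)
        assert cv.attrs["selected"] == 2

    def test_contiguous_blocks(self, rng):
        """Fold i tests the i-th contiguous quarter: plant a strong linear
        relation everywhere except rows 225..299.  The fold whose held-out
        rows are the unrelated block cannot generalize and scores worst."""
        n = 300
        X = rng.standard_normal((n, 4))
        Y = X + 0.2 * rng.standard_normal((n, 4))
        Y[225:] = rng.standard_normal((75, 4))
        cv = cross_validate_cca(X, Y, n_folds=4, component_grid=[1])
        scores = cv.loc[0, "scores"]
        assert np.argmin(scores) == 3
        assert scores[3] < 0.2 < min(scores[:3])

    def test_row_count_validation(self, rng):
        X = rng.standard_normal((10, 3))
        with pytest.raises(ValueError):
            cross_validate_cca(X, X, n_folds=4)
        with pytest.raises(ValueError):
            cross_validate_cca(X[:3], X[:3], n_folds=4)

    def test_training_score_gains_stop_at_planted_rank(self):
        """With two planted latents the training score jumps when the second
        component is added and changes only marginally beyond the true rank
        (components past it carry no shared structure)."""
        d = generate_wrp(SurrogateSpec(n_samples=200, rho_wr=(0.9, 0.7),
                                       rho_rp=(0.9,), seed=8))
        train_scores = []
        for k in range(1, 6):
            m = cca_fit(d.W, d.R, k)
            train_scores.append(cca_score(m, d.W, d.R))
        assert train_scores[1] > train_scores[0] + 0.02
        assert np.all(np.abs(np.diff(train_scores[1:])) < 0.05)


class TestLoadings:
    def test_single_variable_block_loads_fully(self, rng):
        X = rng.standard_normal((80, 1))
        Y = X + 0.1 * rng.standard_normal((80, 1))
        m = cca_fit(X, Y, 1)
        lx, ly = canonical_loadings(m, X, Y)
        assert abs(lx.values[0, 0]) == pytest.approx(1.0, abs=1e-9)

    def test_loadings_equal_brute_force_correlations(self, rng):
        d = generate_wrp(SurrogateSpec(n_samples=120, seed=2))
        m = cca_fit(d.R, d.P, 3)
        lx, ly = canonical_loadings(m, d.R, d.P)
        assert lx.values.shape == (16, 3)
        assert ly.values.shape == (4, 3)
        xs, ys = m.transform(d.R, d.P)
        for j in range(16):
            for c in range(3):
                assert lx.values[j, c] == pytest.approx(
                    np.corrcoef(d.R[:, j], xs[:, c])[0, 1])
        assert np.all(np.abs(lx.values) <= 1.0 + 1e-12)


class TestSensitivityNormalization:
    def test_centering_and_linearity(self):
        P = np.array([[1.2, 0.1, 0.05, 0.45],
                      [1.8, -0.1, 0.15, 0.55],
                      [1.5, 0.0, 0.10, 0.50]])
        Pn, scale = sensitivity_normalize(P, n_runs=2000, seed=0)
        assert np.allclose(Pn.mean(axis=0), 0.0, atol=1e-12)
        P2 = scale.means + 2.0 * (P - scale.means)
        Pn2, _ = sensitivity_normalize(P2, n_runs=2000, seed=0,
                                       reference=scale.means)
        assert np.allclose(Pn2, 2.0 * Pn, atol=1e-9)

    def test_boundary_and_onset_sensitivities_positive(self):
        P = np.array([[1.4, 0.0, 0.08, 0.5], [1.6, 0.0, 0.12, 0.5]])
        _, scale = sensitivity_normalize(P, n_runs=20_000, seed=1)
        assert scale.deltas[0] > 0    # larger boundary -> longer RT
        assert scale.deltas[2] > 0    # later onset -> longer RT
        assert scale.deltas[2] == pytest.approx(1.0, abs=0.05)

    def test_boundary_delta_matches_driftless_closed_form(self):
        """At zero drift the mean RT is z a (a - z a) + t, so the centered
        difference of the closed form is an oracle for Delta_a."""
        ref = np.array([1.5, 0.0, 0.1, 0.5])
        P = np.vstack([ref, ref])
        _, scale = sensitivity_normalize(P, h=0.1, n_runs=60_000, seed=2,
                                         reference=ref)
        z, h, a = ref[3], 0.1, ref[0]
        closed = (z * (a + h) * ((a + h) - z * (a + h))
                  - z * (a - h) * ((a - h) - z * (a - h))) / (2 * h)
        assert scale.deltas[0] == pytest.approx(closed, abs=0.05)


class TestClustering:
    def test_two_blobs_select_k2(self, rng):
        pts = np.vstack([rng.normal(0, 0.2, (60, 3)), rng.normal(4, 0.2, (60, 3))])
        results, K = kmeans_with_silhouette(pts, range(2, 7), seed=0)
        assert K == 2
        assert results[2].silhouette > 0.8

    def test_silhouette_matches_brute_force_four_points(self):
        pts = np.array([[0.0, 0.0], [0.0, 1.0], [8.0, 0.0], [8.0, 1.0]])
        labels = np.array([0, 0, 1, 1])
        from sklearn.metrics import silhouette_score
        assert silhouette_score(pts, labels) == pytest.approx(
            silhouette_brute_force(pts, labels))

    def test_k1_skipped_with_warning(self, rng):
        pts = rng.standard_normal((30, 2))
        with pytest.warns(UserWarning):
            results, _ = kmeans_with_silhouette(pts, (1, 2, 3), seed=0)
        assert 1 not in results


class TestFrontEnd:
    def test_full_analysis_on_surrogate(self):
        d = generate_wrp(SurrogateSpec(n_samples=200, seed=6))
        res = ControlEnsembleAnalysis(d).fit(seed=0, sensitivity_runs=2000)
        assert res.selected_wr == 3
        assert res.selected_rp == 3
        assert res.loadings_rp[0].values.shape[1] == 3
        assert res.selected_K in res.clustering
        assert "3 components" in res.summary()

    def test_mismatched_rows_rejected(self, rng):
        with pytest.raises(ValueError):
            FeatureMatrices(W=rng.standard_normal((10, 14)),
                            R=rng.standard_normal((9, 16)),
                            P=rng.standard_normal((10, 4)))
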