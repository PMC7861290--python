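import numpy as np
import pandas as pd
import pytest

from accdist.evalstats import (
    FormantPoint,
    bark,
    classical_mds,
    evaluate,
    fit_regression,
    formant_distance,
    pearson,
    steiger_test,
)


class TestPearson:
    def test_perfect_positive(self, rng):
        x = rng.standard_normal(20)
        r, p = pearson(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_perfect_negative(self, rng):
        x = rng.standard_normal(20)
        r, _ = pearson(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_covariance_formula(self, rng):
        x, y = rng.standard_normal(50), rng.standard_normal(50)
        r, _ = pearson(x, y)
        expected = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert r == pytest.approx(expected, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson(np.ones(10), np.arange(10.0))


class TestRegression:
    def test_noiseless_planted_coefficients_recovered(self, rng):
        n = 40
        df = pd.DataFrame({"a": rng.standard_normal(n), "b": rng.standard_normal(n)})
        df["y"] = 3.0 - 2.0 * df.a + 0.5 * df.b
        res = fit_regression(df, "y", ["a", "b"])
        np.testing.assert_allclose(res.table["estimate"], [3.0, -2.0, 0.5], atol=1e-10)
        assert res.r_squared == pytest.approx(1.0)

    def test_single_predictor_r_squared_equals_pearson_squared(self, rng):
        n = 60
        df = pd.DataFrame({"x": rng.standard_normal(n)})
        df["y"] = df.x + 0.5 * rng.standard_normal(n)
        res = fit_regression(df, "y", ["x"])
        r, _ = pearson(df.x, df.y)
        assert res.r_squared == pytest.approx(r**2, abs=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        n = 100
        X = rng.standard_normal((n, 3))
        y = X @ [1.0, -2.0, 0.3] + rng.standard_normal(n)
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["y"] = y
        res = fit_regression(df, "y", ["a", "b", "c"])
        Xd = np.column_stack([np.ones(n), X])
        beta = np.linalg.solve(Xd.T @ Xd, Xd.T @ y)
        np.testing.assert_allclose(res.table["estimate"], beta, atol=1e-8)
        resid = y - Xd @ beta
        sigma2 = resid @ resid / (n - 4)
        se = np.sqrt(np.diag(sigma2 * np.linalg.inv(Xd.T @ Xd)))
        np.testing.assert_allclose(res.table["std_error"], se, atol=1e-8)

    def test_t_is_estimate_over_stderr(self, rng):
        df = pd.DataFrame({"x": rng.standard_normal(30)})
        df["y"] = df.x + rng.standard_normal(30)
        res = fit_regression(df, "y", ["x"])
        np.testing.assert_allclose(
            res.table["t_value"],
            res.table["estimate"] / res.table["std_error"],
            atol=1e-6,
        )

    def test_collinear_columns_named(self, rng):
        df = pd.DataFrame({"a": rng.standard_normal(20)})
        df["b"] = 2 * df.a
        df["y"] = rng.standard_normal(20)
        with pytest.raises(ValueError, match="collinear"):
            fit_regression(df, "y", ["a", "b"])


class TestSteiger:
    def test_equal_correlations_give_zero(self):
        z, p = steiger_test(0.5, 0.5, 0.3, n=80)
        assert z == 0.0
        assert p == pytest.approx(1.0)

    def test_antisymmetric_in_compared_pair(self):
        z1, _ = steiger_test(0.7, 0.5, 0.6, n=100)
        z2, _ = steiger_test(0.5, 0.7, 0.6, n=100)
        assert z1 == pytest.approx(-z2, abs=1e-12)

    def test_larger_n_gives_larger_z(self):
        z_small, _ = steiger_test(0.7, 0.5, 0.6, n=50)
        z_large, _ = steiger_test(0.7, 0.5, 0.6, n=500)
        assert abs(z_large) > abs(z_small)

    def test_degenerate_correlation_rejected(self):
        with pytest.raises(ValueError):
            steiger_test(1.0, 0.5, 0.5, n=50)

    def test_rejection_rate_against_simulated_truth(self):
        # rho12 != rho13 planted: the test should reject H0 far more often
        # than alpha; with rho12 = rho13 it should hold the alpha level.
        rng = np.random.default_rng(99)

        def rejection_rate(rho12, rho13, rho23, n=120, reps=300):
            C = np.array([[1, rho12, rho13], [rho12, 1, rho23], [rho13, rho23, 1]])
            L = np.linalg.cholesky(C)
            hits = 0
            for _ in range(reps):
                X = rng.standard_normal((n, 3)) @ L.T
                R = np.corrcoef(X.T)
                _, p = steiger_test(R[0, 1], R[0, 2], R[1, 2], n)
                hits += p < 0.05
            return hits / reps

        assert rejection_rate(0.8, 0.3, 0.4) > 0.9
        assert rejection_rate(0.5, 0.5, 0.5) < 0.12


class TestBarkAndFormants:
    def test_zero_frequency(self):
        assert bark(0.0) == pytest.approx(-0.53)

    def test_half_saturation_point(self):
        assert bark(1960.0) == pytest.approx(26.81 / 2 - 0.53)

    @pytest.mark.parametrize("formula", ["traunmuller", "zwicker"])
    def test_monotone(self, formula):
        f = np.linspace(0, 8000, 200)
        z = bark(f, formula)
        assert np.all(np.diff(z) > 0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            bark(-10.0)

    def test_formant_distance_identity_and_symmetry(self):
        a = FormantPoint(500, 1500)
        b = FormantPoint(300, 2200)
        assert formant_distance(a, a) == 0.0
        assert formant_distance(a, b) == pytest.approx(formant_distance(b, a))

    def test_f1_only_offset_reduces_to_1d(self):
        a = FormantPoint(400, 1500)
        b = FormantPoint(600, 1500)
        assert formant_distance(a, b) == pytest.approx(abs(bark(400) - bark(600)))


class TestClassicalMds:
    def test_zero_matrix_collapses_to_origin(self):
        X, _ = classical_mds(np.zeros((5, 5)), k=2)
        np.testing.assert_allclose(X, 0.0, atol=1e-12)

    def test_planted_2d_configuration_recovered(self, rng):
        pts = rng.standard_normal((4, 2)) * 3
        D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        X, explained = classical_mds(D, k=2)
        D2 = np.linalg.norm(X[:, None] - X[None, :], axis=-1)
        np.testing.assert_allclose(D2, D, atol=1e-8)
        assert explained.sum() == pytest.approx(1.0, abs=1e-8)

    def test_collinear_points_one_dimension(self):
        t = np.array([0.0, 1.0, 2.5, 4.0])
        D = np.abs(t[:, None] - t[None, :])
        _, explained = classical_mds(D, k=2)
        assert explained[0] == pytest.approx(1.0, abs=1e-10)
        assert explained[1] == pytest.approx(0.0, abs=1e-10)

    def test_asymmetric_rejected(self):
        D = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            classical_mds(D)


class TestEvaluate:
    @staticmethod
    def _tables(n=12, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"s{i}" for i in range(n)]
        dist = rng.uniform(2, 6, n)
        return (
            pd.DataFrame({"target_speaker_id": ids, "mean_distance": dist}),
            pd.DataFrame({"speaker_id": ids, "mean_rating": 7 - dist}),
        )

    def test_strictly_decreasing_relation_gives_minus_one(self):
        distances, ratings = self._tables()
        report = evaluate(distances, ratings)
        assert report["pearson_r"] == pytest.approx(-1.0)

    def test_regression_and_steiger_blocks_present(self, rng, tmp_path):
        distances, ratings = self._tables(n=30, seed=1)
        ratings = ratings.assign(
            mean_rating=(ratings.mean_rating + 0.3 * rng.standard_normal(30)).clip(1, 7)
        )
        transcription = pd.DataFrame({
            "speaker_id": distances.target_speaker_id,
            "distance": distances.mean_distance * 0.1 + rng.standard_normal(30) * 0.05,
        })
        out = tmp_path / "report.json"
        report = evaluate(distances, ratings, transcription=transcription, out_json=out)
        assert "regression" in report and "steiger" in report
        assert out.exists()
        assert report["regression"]["n"] == 30

    def test_duplicated_speakers_rejected(self):
        distances, ratings = self._tables()
        dup = pd.concat([distances, distances.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicated"):
            evaluate(dup, ratings)
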