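import numpy as np
import pandas as pd
import pytest

from dyadlds.sem import (
    ModelSpec,
    ParamIndex,
    GroupData,
    fit_ml,
    fml_discrepancy,
    weighted_moments,
    em_saturated,
    fit_indices_from,
    srmr,
    chisq_diff,
    NotPositiveDefiniteError,
)
from dyadlds.sem.estimate import _MomentsObjective, _FimlObjective

from conftest import one_factor_spec, simulate_factor_data


class TestDiscrepancy:
    def test_zero_at_truth(self):
        S = np.array([[2.0, 0.5], [0.5, 1.0]])
        m = np.array([0.3, -0.2])
        assert fml_discrepancy(S, m, S.copy(), m.copy()) == pytest.approx(0.0, abs=1e-12)

    def test_scalar_case(self):
        # p=1: S=2, Sigma=1 -> log1 + 2 - log2 - 1 = 1 - log2
        val = fml_discrepancy(np.array([[2.0]]), np.zeros(1), np.array([[1.0]]), np.zeros(1))
        assert val == pytest.approx(1.0 - np.log(2.0))

    def test_mean_term_quadratic(self):
        S = np.eye(3)
        base = fml_discrepancy(S, np.zeros(3), np.eye(3), np.zeros(3))
        shifted = fml_discrepancy(S, np.array([1.0, 0, 0]), np.eye(3), np.zeros(3))
        assert shifted - base == pytest.approx(1.0)

    def test_non_pd_named(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(NotPositiveDefiniteError, match="Sigma"):
            fml_discrepancy(np.eye(2), np.zeros(2), bad, np.zeros(2))
        with pytest.raises(NotPositiveDefiniteError, match="S"):
            fml_discrepancy(bad, np.zeros(2), np.eye(2), np.zeros(2))

    def test_positive_away_from_truth(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            A = rng.normal(size=(3, 3))
            S = A @ A.T + np.eye(3)
            assert fml_discrepancy(S, rng.normal(size=3), np.eye(3), np.zeros(3)) > 0


class TestGradient:
    def test_analytic_matches_numeric_at_random_theta(self):
        spec = one_factor_spec(["y1", "y2", "y3", "y4"])
        rng = np.random.default_rng(42)
        frame, _ = simulate_factor_data(
            rng, 400, [1, 0.9, 1.1, 0.8], [0, 0.2, -0.1, 0.3], [0.7] * 4
        )
        index = ParamIndex([spec])
        gd = GroupData.from_frame(frame, spec.observed)
        for Obj in (_MomentsObjective, _FimlObjective):
            obj = Obj(index, [gd])
            theta = index.start + rng.normal(0, 0.05, index.n_free)
            _, grad = obj.value_and_grad(theta)
            num = np.zeros_like(grad)
            for j in range(len(theta)):
                h = 1e-6 * (1 + abs(theta[j]))
                tp, tm = theta.copy(), theta.copy()
                tp[j] += h
                tm[j] -= h
                num[j] = (obj.value_and_grad(tp)[0] - obj.value_and_grad(tm)[0]) / (2 * h)
            np.testing.assert_allclose(grad, num, atol=1e-5 * max(1, np.abs(num).max()))


class TestFitML:
    def test_three_indicator_closed_form(self, factor_frame):
        spec = one_factor_spec(["y1", "y2", "y3"])
        table, fit = fit_ml(spec, factor_frame)
        S, m, _ = weighted_moments(factor_frame.to_numpy(), np.ones(len(factor_frame)))
        psi = S[0, 1] * S[0, 2] / S[1, 2]
        lam2, lam3 = S[1, 2] / S[0, 2], S[1, 2] / S[0, 1]
        assert fit.stat == pytest.approx(0.0, abs=1e-6)
        assert fit.cfi == pytest.approx(1.0, abs=1e-9)
        assert table.get(0, "psi", "f", "f").value == pytest.approx(psi, abs=1e-6)
        assert table.get(0, "lambda", "y2", "f").value == pytest.approx(lam2, abs=1e-6)
        assert table.get(0, "lambda", "y3", "f").value == pytest.approx(lam3, abs=1e-6)
        assert table.get(0, "alpha", "f").value == pytest.approx(m[0], abs=1e-6)
        assert table.get(0, "nu", "y2").value == pytest.approx(m[1] - lam2 * m[0], abs=1e-6)

    def test_unit_weights_equal_unweighted(self, factor_frame):
        spec = one_factor_spec(["y1", "y2", "y3"])
        t1, _ = fit_ml(spec, factor_frame)
        t2, _ = fit_ml(spec, factor_frame, weights=np.ones(len(factor_frame)))
        np.testing.assert_allclose(t1.theta, t2.theta, atol=1e-8)

    def test_fiml_equals_moments_on_complete_data(self, factor_frame):
        spec = one_factor_spec(["y1", "y2", "y3"])
        t1, f1 = fit_ml(spec, factor_frame, mode="moments")
        t2, f2 = fit_ml(spec, factor_frame, mode="fiml")
        np.testing.assert_allclose(t1.theta, t2.theta, atol=1e-5)
        assert f1.stat == pytest.approx(f2.stat, abs=1e-3)

    def test_saturated_model_recovers_weighted_moments(self):
        rng = np.random.default_rng(7)
        frame, _ = simulate_factor_data(rng, 300, [1, 1.2], [0, 0.4], [0.6, 0.6])
        w = rng.uniform(0.5, 2.0, 300)
        cols = ["y1", "y2"]
        spec = ModelSpec(cols, [])
        for c in cols:
            spec.add("nu", c, free=True, value=0.0)
        spec.add("theta", "y1", "y1", free=True, value=1.0)
        spec.add("theta", "y2", "y2", free=True, value=1.0)
        spec.add("theta", "y1", "y2", free=True, value=0.0)
        table, fit = fit_ml(spec, frame, weights=w)
        S, m, _ = weighted_moments(frame[cols].to_numpy(), w)
        assert fit.stat == pytest.approx(0.0, abs=1e-7)
        assert fit.saturated
        assert table.get(0, "nu", "y1").value == pytest.approx(m[0], abs=1e-7)
        assert table.get(0, "theta", "y1", "y2").value == pytest.approx(S[0, 1], abs=1e-7)

    def test_reordering_observed_variables_invariant(self, factor_frame):
        cols = ["y1", "y2", "y3"]
        spec = one_factor_spec(cols)
        _, fit1 = fit_ml(spec, factor_frame)
        # marker stays y1; remaining variables swap
        spec2 = one_factor_spec(["y1", "y3", "y2"])
        _, fit2 = fit_ml(spec2, factor_frame[["y1", "y3", "y2"]])
        assert fit1.stat == pytest.approx(fit2.stat, abs=1e-6)
        assert fit1.cfi == pytest.approx(fit2.cfi, abs=1e-8)

    def test_too_few_cases_rejected(self):
        spec = one_factor_spec(["y1", "y2", "y3"])
        frame = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 3)),
                             columns=["y1", "y2", "y3"])
        with pytest.raises(ValueError, match="fewer cases"):
            fit_ml(spec, frame)

    def test_heywood_warns(self):
        # anti-correlated specific factors in y2/y3 push the closed-form
        # marker residual variance negative -> estimate pinned at the floor
        rng = np.random.default_rng(1)
        n = 500
        eta = rng.normal(0, 1, n)
        u = rng.normal(0, np.sqrt(0.5), n)
        frame = pd.DataFrame({
            "y1": eta + rng.normal(0, np.sqrt(0.05), n),
            "y2": eta + u,
            "y3": eta - u,
        })
        spec = one_factor_spec(["y1", "y2", "y3"])
        with pytest.warns(UserWarning, match="Heywood"):
            table, fit = fit_ml(spec, frame)
        assert any("bound" in w for w in fit.warnings)


class TestFIMLMissing:
    def test_em_saturated_matches_complete_case_truth(self):
        rng = np.random.default_rng(5)
        n = 4000
        mu = np.array([0.5, -0.3, 1.0])
        A = np.array([[1.0, 0.3, 0.2], [0.3, 1.2, 0.4], [0.2, 0.4, 0.8]])
        y = rng.multivariate_normal(mu, A, size=n)
        ymiss = y.copy()
        ymiss[rng.random((n, 3)) < 0.2] = np.nan
        keep = ~np.isnan(ymiss).all(axis=1)
        gd = GroupData(ymiss[keep], np.ones(keep.sum()), ["a", "b", "c"])
        mu_hat, sig_hat, ll = em_saturated(gd)
        np.testing.assert_allclose(mu_hat, mu, atol=0.1)
        np.testing.assert_allclose(sig_hat, A, atol=0.15)

    def test_fiml_unbiased_under_mcar(self):
        # reduced-scale version of the 200-replication check
        rng = np.random.default_rng(21)
        loads = [1.0, 0.9, 1.1, 0.8]
        reps, n = 30, 1500
        est = []
        for r in range(reps):
            frame, _ = simulate_factor_data(
                rng, n, loads, [0, 0.2, -0.1, 0.3], [0.7] * 4,
                factor_mean=0.5, factor_sd=1.0,
            )
            arr = frame.to_numpy()
            arr[rng.random(arr.shape) < 0.10] = np.nan
            fm = pd.DataFrame(arr, columns=frame.columns)
            spec = one_factor_spec(list(frame.columns))
            table, fit = fit_ml(spec, fm, mode="fiml", compute_se=False)
            est.append([
                table.get(0, "lambda", "y2", "f").value,
                table.get(0, "psi", "f", "f").value,
                table.get(0, "alpha", "f").value,
            ])
        est = np.array(est)
        truth = np.array([0.9, 1.0, 0.5])
        mc_se = est.std(axis=0) / np.sqrt(reps)
        assert np.all(np.abs(est.mean(axis=0) - truth) < 3 * mc_se)


class TestIndices:
    def test_perfect_fit(self):
        cfi, rmsea = fit_indices_from(5.0, 10, 200.0, 20, 1000, 1)
        assert cfi == 1.0 and rmsea == 0.0

    def test_rmsea_arithmetic(self):
        _, rmsea = fit_indices_from(20.0, 10, 500.0, 20, 1000, 1)
        assert rmsea == pytest.approx(np.sqrt(10 / 10000))

    def test_cfi_arithmetic(self):
        cfi, _ = fit_indices_from(30.0, 5, 110.0, 10, 500, 1)
        # T-df=25, T0-df0=100
        assert cfi == pytest.approx(0.75)

    def test_multigroup_multiplier(self):
        _, r1 = fit_indices_from(20.0, 10, 500.0, 20, 1000, 1)
        _, r2 = fit_indices_from(20.0, 10, 500.0, 20, 1000, 2)
        assert r2 == pytest.approx(r1 * np.sqrt(2))

    def test_df0_smaller_than_df_rejected(self):
        with pytest.raises(ValueError):
            fit_indices_from(10, 20, 5, 10, 100, 1)


class TestSRMR:
    def test_zero_at_perfect_fit(self):
        S = np.array([[1.0, 0.3], [0.3, 1.0]])
        assert srmr(S, S.copy()) == 0.0

    def test_hand_arithmetic(self):
        # p=2, correlation residual 0.1 off-diagonal, exact variances
        S = np.array([[1.0, 0.3], [0.3, 1.0]])
        sigma = np.array([[1.0, 0.2], [0.2, 1.0]])
        assert srmr(S, sigma) == pytest.approx(np.sqrt(0.01 / 3))

    def test_scale_invariance(self):
        S = np.array([[1.0, 0.3], [0.3, 1.0]])
        sigma = np.array([[1.0, 0.2], [0.2, 1.0]])
        D = np.diag([10.0, 1.0])
        assert srmr(D @ S @ D, D @ sigma @ D) == pytest.approx(srmr(S, sigma))


class TestChisqDiff:
    def test_identical_fits_zero(self, factor_frame):
        spec = one_factor_spec(["y1", "y2", "y3"])
        _, fit = fit_ml(spec, factor_frame)
        d = chisq_diff(fit, fit)
        assert d.d_stat == 0 and d.d_df == 0 and d.d_cfi == 0 and d.d_rmsea == 0

    def test_non_nested_rejected(self, factor_frame):
        spec = one_factor_spec(["y1", "y2", "y3"])
        _, fit_parent = fit_ml(spec, factor_frame)
        spec_c = one_factor_spec(["y1", "y2", "y3"])
        spec_c.relabel("lambda", "y2", "f", label="eq")
        spec_c.relabel("lambda", "y3", "f", label="eq")
        _, fit_nested = fit_ml(spec_c, factor_frame)
        with pytest.raises(ValueError):
            chisq_diff(fit_parent, fit_nested)  # arguments swapped
        d = chisq_diff(fit_nested, fit_parent)
        assert d.d_df == 1 and d.d_stat >= 0

    def test_null_distribution_mean(self):
        # constrained model true: Delta-T over replications ~ chi2(1), mean ~ 1
        rng = np.random.default_rng(17)
        reps = 120
        deltas = []
        for r in range(reps):
            frame, _ = simulate_factor_data(
                rng, 250, [1.0, 0.9, 0.9], [0.0, 0.1, 0.1], [0.7] * 3
            )
            free = one_factor_spec(["y1", "y2", "y3"])
            cons = one_factor_spec(["y1", "y2", "y3"])
            cons.relabel("lambda", "y2", "f", label="eq")
            cons.relabel("lambda", "y3", "f", label="eq")
            _, f_free = fit_ml(free, frame, compute_se=False)
            _, f_cons = fit_ml(cons, frame, compute_se=False)
            deltas.append(chisq_diff(f_cons, f_free).d_stat)
        deltas = np.array(deltas)
        # chi2(1): mean 1, sd sqrt(2); MC SE of the mean = sqrt(2/reps)
        assert abs(deltas.mean() - 1.0) < 3 * np.sqrt(2.0 / reps)


class TestSandwich:
    def test_sandwich_close_to_observed_with_unit_weights(self, factor_frame):
        spec = one_factor_spec(["y1", "y2", "y3"])
        t_obs, _ = fit_ml(spec, factor_frame, se="observed")
        t_sw, _ = fit_ml(spec, factor_frame, se="sandwich")
        se_obs = np.sqrt(np.diag(t_obs.cov))
        se_sw = np.sqrt(np.diag(t_sw.cov))
        np.testing.assert_allclose(se_obs, se_sw, rtol=0.2)

    def test_coverage_with_informative_weights(self):
        # weighted mean structure: coverage of the factor-mean CI (reduced reps)
        rng = np.random.default_rng(33)
        reps, n = 60, 600
        hits = 0
        for r in range(reps):
            frame, eta = simulate_factor_data(
                rng, n, [1.0, 0.9, 1.1], [0.0, 0.1, -0.1], [0.7] * 3,
                factor_mean=0.4, factor_sd=1.0,
            )
            w = np.exp(0.5 * rng.normal(size=n))  # weights independent of y
            spec = one_factor_spec(["y1", "y2", "y3"])
            table, _ = fit_ml(spec, frame, weights=w, se="sandwich")
            est = table.get(0, "alpha", "f")
            assert est.se is not None
            if abs(est.value - 0.4) < 1.96 * est.se:
                hits += 1
        assert 0.88 <= hits / reps <= 1.0
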