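import numpy as np
import pandas as pd
import pytest

from dyadlds import synthetic
from dyadlds.instruments import scored_item_frame
from dyadlds.invariance import joint_cfa_spec, run_ladder
from dyadlds.lds import (
    A_DELTA,
    A_SELF,
    B_DELTA,
    PSI_DD,
    build_lds_spec,
    spec_from_invariance,
    fit_lds,
    fit_conditional_lds,
    conditional_group_estimates,
    stars,
)
from dyadlds.sem import GroupData, ParamIndex, fit_ml, implied_moments
from dyadlds.invariance import LadderError


ALL_EQ = frozenset(range(1, 5))


def continuous_frame(n=3000, seed=0, delta_std=-0.5, covariates=False, **cc_kw):
    cfg = synthetic.default_config(
        n_dyads=n, seed=seed, constructs=("conduct",), with_covariates=covariates
    )
    cfg.continuous_items = True
    cc = cfg.constructs["conduct"]
    cc.mean_delta = delta_std * cc.sd_delta
    for k, v in cc_kw.items():
        setattr(cc, k, v)
    frame, truth = synthetic.generate_dyads(cfg)
    return frame, truth, cfg


class TestSpecConstruction:
    def test_implied_parent_mean_is_self_plus_delta(self):
        spec = build_lds_spec("conduct", ALL_EQ, ALL_EQ)
        index = ParamIndex([spec])
        theta = index.start.copy()
        theta[index.theta_index(0, "alpha", "fS")] = 0.7
        theta[index.theta_index(0, "alpha", "d")] = -0.3
        mom = implied_moments(index, 0, theta)
        assert mom.eta_mean[spec.latents.index("fP")] == pytest.approx(0.4)

    def test_df_matches_cfa(self):
        # reparameterization adds no free parameters beyond the CFA's moments
        lds = build_lds_spec("conduct", ALL_EQ, ALL_EQ)
        cfa = joint_cfa_spec("conduct", ALL_EQ, ALL_EQ)
        assert len(ParamIndex([lds]).labels) == len(ParamIndex([cfa]).labels)

    def test_fixed_delta_mean_is_nested_equal_means_model(self):
        frame, _, _ = continuous_frame(n=1500, seed=3)
        free_spec = build_lds_spec("conduct", ALL_EQ, ALL_EQ)
        fixed_spec = build_lds_spec("conduct", ALL_EQ, ALL_EQ, fix_delta_mean=True)
        _, fit_free = fit_ml(free_spec, frame_data(frame), compute_se=False)
        _, fit_fixed = fit_ml(fixed_spec, frame_data(frame), compute_se=False)
        assert fit_fixed.df == fit_free.df + 1
        assert fit_fixed.stat >= fit_free.stat - 1e-8

    def test_invariance_gate_enforced(self):
        cfg = synthetic.invariance_scenario_config(
            n_dyads=2000, seed=5, noninvariance=[(2, "intercept", 0.6)]
        )
        frame, _ = synthetic.generate_dyads(cfg)
        rep = run_ladder(frame, "conduct", max_free=0)
        assert not rep.invariant
        with pytest.raises(LadderError):
            spec_from_invariance(rep)

    def test_carries_freed_items_verbatim(self):
        cfg = synthetic.invariance_scenario_config(
            n_dyads=3000, seed=6, noninvariance=[(3, "intercept", 0.45)]
        )
        frame, _ = synthetic.generate_dyads(cfg)
        rep = run_ladder(frame, "conduct")
        spec = spec_from_invariance(rep)
        freed_col = spec.observed[5 + 3]  # parent item at released position
        cell = spec.get("nu", freed_col)
        assert cell.free and cell.label is None  # reporter-specific
        other = spec.get("nu", spec.observed[5 + 1])
        assert other.label is not None  # still equality constrained

    def test_nonbinary_covariate_rejected(self):
        frame, _, _ = continuous_frame(n=300, seed=8)
        frame = frame.copy()
        frame["grade"] = np.arange(len(frame)) % 3
        spec = build_lds_spec("conduct", ALL_EQ, ALL_EQ, covariate="grade")
        with pytest.raises(ValueError, match="binary"):
            fit_conditional_lds(frame, spec, "conduct", "grade")


def frame_data(frame):
    data = pd.concat(
        [scored_item_frame(frame, "conduct", "self"),
         scored_item_frame(frame, "conduct", "parent")], axis=1
    )
    return [GroupData(data.to_numpy(float), np.ones(len(data)), list(data.columns))]


class TestUnconditional:
    def test_reparameterization_identity(self):
        frame, _, _ = continuous_frame(n=2500, seed=11)
        lds_spec = build_lds_spec("conduct", ALL_EQ, ALL_EQ)
        cfa_spec = joint_cfa_spec("conduct", ALL_EQ, ALL_EQ)
        res = fit_lds(frame, lds_spec, "conduct")
        cfa_table, cfa_fit = fit_ml([cfa_spec], frame_data(frame))
        assert res.fit.loglik == pytest.approx(cfa_fit.loglik, abs=1e-5)
        a_diff = cfa_table.get(0, "alpha", "fP").value - cfa_table.get(0, "alpha", "fS").value
        assert res.mean_raw == pytest.approx(a_diff, abs=1e-6)

    def test_sign_contract_parents_lower(self):
        frame, _, _ = continuous_frame(n=2500, seed=12, delta_std=-0.9)
        spec = build_lds_spec("conduct", ALL_EQ, ALL_EQ)
        res = fit_lds(frame, spec, "conduct")
        assert res.mean_raw < 0 and res.mean_std < 0

    def test_standardization_consistency(self):
        frame, _, _ = continuous_frame(n=2000, seed=13)
        spec = build_lds_spec("conduct", ALL_EQ, ALL_EQ)
        res = fit_lds(frame, spec, "conduct")
        assert res.mean_std * np.sqrt(res.variance) == pytest.approx(res.mean_raw, abs=1e-8)
        assert abs(res.covariance_std) <= 1.0
        assert res.variance > 0

    def test_recovery_at_paper_scale(self):
        frame, _, cfg = continuous_frame(n=6700, seed=14, delta_std=-0.9)
        cc = cfg.constructs["conduct"]
        spec = build_lds_spec("conduct", ALL_EQ, ALL_EQ)
        res = fit_lds(frame, spec, "conduct")
        assert res.mean_std == pytest.approx(-0.9, abs=3 * res.mean_std_se)
        true_cov_std = cc.cov_self_delta / (cc.sd_self * cc.sd_delta)
        assert res.covariance_std == pytest.approx(
            true_cov_std, abs=3 * res.covariance_std_se
        )

    def test_zero_difference_degenerate_flagged(self):
        from dyadlds.instruments import item_columns

        frame, _, _ = continuous_frame(n=800, seed=15)
        # parent items copy the self items (tiny jitter keeps S invertible)
        rng = np.random.default_rng(1)
        for s_col, p_col in zip(item_columns("conduct", "self"),
                                item_columns("conduct", "parent")):
            frame[p_col] = frame[s_col] + rng.normal(0, 1e-3, len(frame))
        spec = build_lds_spec("conduct", ALL_EQ, ALL_EQ)
        with pytest.warns(UserWarning, match="Heywood"):
            res = fit_lds(frame, spec, "conduct")
        assert res.degenerate
        assert np.isnan(res.mean_std)
        assert abs(res.mean_raw) < 0.05

    def test_stars_thresholds(self):
        assert stars(0.04) == "*"
        assert stars(0.009) == "**"
        assert stars(0.0009) == "***"
        assert stars(0.2) == ""


class TestConditional:
    def test_group_estimate_arithmetic(self):
        # raw intercept -0.2, beta -0.1, phi 0.09 -> -0.667 and -1.0
        frame, _, _ = continuous_frame(n=500, seed=21, covariates=True)
        spec = build_lds_spec("conduct", ALL_EQ, ALL_EQ, covariate="sex")
        res = fit_conditional_lds(frame, spec, "conduct", "sex")
        tab = res.table
        idx = {lab: i for i, lab in enumerate(tab.index.labels)}
        theta = tab.theta.copy()
        theta[idx[A_DELTA]] = -0.2
        theta[idx[B_DELTA]] = -0.1
        theta[idx[PSI_DD]] = 0.09
        tab.theta = theta
        ref, _ = tab.delta_method(lambda v: (v[0] + 0 * v[1]) / np.sqrt(v[2]),
                                  [A_DELTA, B_DELTA, PSI_DD])
        oth, _ = tab.delta_method(lambda v: (v[0] + 1 * v[1]) / np.sqrt(v[2]),
                                  [A_DELTA, B_DELTA, PSI_DD])
        assert ref == pytest.approx(-0.2 / 0.3, abs=1e-9)
        assert oth == pytest.approx(-1.0, abs=1e-9)

    def test_level_difference_equals_beta_raw(self):
        frame, _, _ = continuous_frame(n=2500, seed=22, covariates=True)
        spec = build_lds_spec("conduct", ALL_EQ, ALL_EQ, covariate="sex")
        res = fit_conditional_lds(frame, spec, "conduct", "sex")
        raw_diff = (res.other.value - res.reference.value) * np.sqrt(
            res.table.estimate(PSI_DD)
        )
        assert raw_diff == pytest.approx(res.beta_delta, abs=1e-8)

    def test_beta_recovery(self):
        cfg = synthetic.default_config(
            n_dyads=6700, seed=23, constructs=("conduct",), with_covariates=True
        )
        cfg.continuous_items = True
        cfg.covariates = {"sex": synthetic.CovariateEffect(0.5, beta_self=-0.2,
                                                           beta_delta=-0.3)}
        frame, _ = synthetic.generate_dyads(cfg)
        spec = build_lds_spec("conduct", ALL_EQ, ALL_EQ, covariate="sex")
        res = fit_conditional_lds(frame, spec, "conduct", "sex")
        assert res.beta_delta == pytest.approx(-0.3, abs=3 * res.beta_delta_se)
        assert res.beta_self == pytest.approx(-0.2, abs=3 * res.beta_self_se)

    def test_null_effect_levels_agree(self):
        cfg = synthetic.default_config(
            n_dyads=4000, seed=24, constructs=("conduct",), with_covariates=True
        )
        cfg.continuous_items = True
        cfg.covariates = {"sex": synthetic.CovariateEffect(0.5)}
        frame, _ = synthetic.generate_dyads(cfg)
        spec = build_lds_spec("conduct", ALL_EQ, ALL_EQ, covariate="sex")
        res = fit_conditional_lds(frame, spec, "conduct", "sex")
        assert abs(res.other.value - res.reference.value) < 3 * np.hypot(
            res.other.se, res.reference.se
        )

    def test_delta_ci_close_to_bootstrap(self):
        # parametric bootstrap oracle for the standardized level estimate
        frame, _, _ = continuous_frame(n=2500, seed=25, covariates=True)
        spec = build_lds_spec("conduct", ALL_EQ, ALL_EQ, covariate="sex")
        res = fit_conditional_lds(frame, spec, "conduct", "sex")
        tab = res.table
        idx = [tab.index.labels.index(l) for l in (A_DELTA, B_DELTA, PSI_DD)]
        mean = tab.theta[idx]
        cov = tab.cov[np.ix_(idx, idx)]
        rng = np.random.default_rng(0)
        draws = rng.multivariate_normal(mean, cov, size=4000)
        draws = draws[draws[:, 2] > 1e-8]
        boot = (draws[:, 0] + draws[:, 1]) / np.sqrt(draws[:, 2])
        lo, hi = np.quantile(boot, [0.025, 0.975])
        width_boot = hi - lo
        width_delta = res.other.ci_high - res.other.ci_low
        assert width_delta == pytest.approx(width_boot, rel=0.10)

    def test_plot_ready_frame(self):
        frame, _, _ = continuous_frame(n=800, seed=26, covariates=True)
        spec = build_lds_spec("conduct", ALL_EQ, ALL_EQ, covariate="sex")
        res = fit_conditional_lds(frame, spec, "conduct", "sex")
        levels = conditional_group_estimates(res)
        assert list(levels["level"]) == ["female", "male"]
        assert (levels["ci_low"] <= levels["estimate"]).all()
        assert {"self_factor_mean", "parent_factor_mean"} <= set(levels.columns)
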