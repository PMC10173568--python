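import numpy as np
import pandas as pd
import pytest

from dyadlds import synthetic
from dyadlds.instruments import (
    item_columns,
    reference_item_moments,
    scored_item_frame,
    k6_columns,
)


def tiny_config(**kw):
    kw.setdefault("n_dyads", 500)
    kw.setdefault("seed", 1)
    kw.setdefault("constructs", ("conduct",))
    kw.setdefault("with_covariates", False)
    return synthetic.default_config(**kw)


class TestConfigValidation:
    def test_invalid_covariance_rejected(self):
        cfg = tiny_config()
        cc = cfg.constructs["conduct"]
        cc.cov_self_delta = 10.0
        with pytest.raises(synthetic.ConfigError, match="cov_self_delta"):
            cfg.validate()

    def test_nonincreasing_thresholds_rejected(self):
        cfg = tiny_config()
        cfg.constructs["conduct"].thresholds_self[0] = (1.0, 0.5)
        with pytest.raises(synthetic.ConfigError, match="thresholds"):
            cfg.validate()

    def test_bad_mcar_rate_rejected(self):
        cfg = tiny_config()
        cfg.missingness.item_mcar_rate = 1.5
        with pytest.raises(synthetic.ConfigError):
            cfg.validate()

    def test_bad_prevalence_rejected(self):
        cfg = tiny_config(with_covariates=True)
        cfg.covariates["sex"].prevalence = -0.1
        with pytest.raises(synthetic.ConfigError):
            cfg.validate()


class TestGenerator:
    def test_deterministic_byte_for_byte(self, tmp_path):
        cfg = tiny_config(seed=9)
        f1, _ = synthetic.generate_dyads(cfg)
        f2, _ = synthetic.generate_dyads(cfg)
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        synthetic.write_dyads_csv(f1, p1)
        synthetic.write_dyads_csv(f2, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_truth_identity_parent_equals_self_plus_delta(self):
        _, truth = synthetic.generate_dyads(tiny_config())
        np.testing.assert_allclose(
            truth.eta_parent["conduct"],
            truth.eta_self["conduct"] + truth.delta["conduct"],
        )

    def test_zero_discrepancy_degenerate_case(self):
        # no discrepancy, no noise, identical measurement -> identical items
        cfg = synthetic.invariance_scenario_config(n_dyads=300, seed=2, delta_std=0.0)
        cc = cfg.constructs["conduct"]
        cc.sd_delta = 1e-12
        cc.mean_delta = 0.0
        cc.cov_self_delta = 0.0
        cc.resid_sd_self = [1e-12] * 5
        cc.resid_sd_parent = [1e-12] * 5
        frame, _ = synthetic.generate_dyads(cfg)
        for s_col, p_col in zip(item_columns("conduct", "self"),
                                item_columns("conduct", "parent")):
            assert (frame[s_col] == frame[p_col]).all()

    def test_delta_mean_lln(self):
        cfg = tiny_config(n_dyads=5000, seed=5)
        cc = cfg.constructs["conduct"]
        cc.mean_delta = -0.5 * cc.sd_delta
        _, truth = synthetic.generate_dyads(cfg)
        d = truth.delta["conduct"]
        mc_se = cc.sd_delta / np.sqrt(len(d))
        assert abs(d.mean() - cc.mean_delta) < 3 * mc_se

    def test_intercept_offset_moves_only_that_item(self):
        base = synthetic.invariance_scenario_config(n_dyads=20000, seed=31)
        off = synthetic.invariance_scenario_config(
            n_dyads=20000, seed=31, noninvariance=[(2, "intercept", 0.6)]
        )
        f0, _ = synthetic.generate_dyads(base)
        f1, _ = synthetic.generate_dyads(off)
        m0 = scored_item_frame(f0, "conduct", "parent").mean()
        m1 = scored_item_frame(f1, "conduct", "parent").mean()
        cols = item_columns("conduct", "parent")
        assert m1[cols[2]] > m0[cols[2]] + 0.05
        for j in (0, 1, 3, 4):
            assert abs(m1[cols[j]] - m0[cols[j]]) < 0.02  # same seed latents

    def test_latent_covariance_converges(self):
        cfg = tiny_config(n_dyads=50000, seed=8)
        cc = cfg.constructs["conduct"]
        _, truth = synthetic.generate_dyads(cfg)
        s, d = truth.eta_self["conduct"], truth.delta["conduct"]
        emp = np.cov(np.vstack([s, d]))
        n = len(s)
        # 3 * MC SE of a covariance estimate, roughly sqrt((v11*v22+v12^2)/n)
        tol = 3 * np.sqrt(
            (cc.sd_self**2 * cc.sd_delta**2 + cc.cov_self_delta**2) / n
        )
        assert abs(emp[0, 0] - cc.sd_self**2) < 3 * cc.sd_self**2 * np.sqrt(2 / n)
        assert abs(emp[1, 1] - cc.sd_delta**2) < 3 * cc.sd_delta**2 * np.sqrt(2 / n)
        assert abs(emp[0, 1] - cc.cov_self_delta) < tol

    def test_ordinal_mean_monotone_in_intercept(self):
        # raising nu for an item never decreases its ordinal mean
        base = synthetic.invariance_scenario_config(n_dyads=20000, seed=13)
        prev = None
        for bump in (0.0, 0.3, 0.8):
            cfg = synthetic.invariance_scenario_config(
                n_dyads=20000, seed=13,
                noninvariance=[(1, "intercept", bump)] if bump else None,
            )
            frame, _ = synthetic.generate_dyads(cfg)
            m = scored_item_frame(frame, "conduct", "parent").mean().iloc[1]
            if prev is not None:
                assert m >= prev - 1e-9
            prev = m

    def test_k6_class_matches_covariate(self):
        cfg = tiny_config(with_covariates=True, n_dyads=2000)
        frame, truth = synthetic.generate_dyads(cfg)
        totals = frame[k6_columns()].sum(axis=1)
        np.testing.assert_array_equal(
            (totals >= 5).astype(int), truth.covariate_values["distress"]
        )
        assert frame[k6_columns()].to_numpy().max() <= 4

    def test_continuous_items_mode(self):
        cfg = tiny_config()
        cfg.continuous_items = True
        frame, _ = synthetic.generate_dyads(cfg)
        vals = frame[item_columns("conduct", "self")].to_numpy()
        assert not np.allclose(vals, np.round(vals))


class TestMissingness:
    def test_no_missingness_when_disabled(self):
        frame, _ = synthetic.generate_dyads(tiny_config())
        assert frame["complete"].eq(1).all()
        assert not frame[item_columns("conduct", "self")].isna().any().any()

    def test_target_completeness_rate(self):
        cfg = tiny_config(n_dyads=5000, with_covariates=True)
        # logit chosen for ~67% marginal completeness
        target = 0.67
        cfg.missingness = synthetic.MissingnessConfig(
            logit_intercept=float(np.log(target / (1 - target)))
        )
        frame, _ = synthetic.generate_dyads(cfg)
        rate = frame["complete"].mean()
        assert abs(rate - target) < 2 * np.sqrt(target * (1 - target) / 5000)

    def test_negative_education_effect_lowers_completeness(self):
        cfg = tiny_config(n_dyads=20000, with_covariates=True)
        cfg.missingness = synthetic.MissingnessConfig(
            logit_intercept=1.0, logit_coefs={"edu": -1.0}
        )
        frame, _ = synthetic.generate_dyads(cfg)
        rate_hi = frame.loc[frame["edu"] == 1, "complete"].mean()
        rate_lo = frame.loc[frame["edu"] == 0, "complete"].mean()
        assert rate_hi < rate_lo

    def test_item_mcar_blanks_cells_and_records_mask(self):
        cfg = tiny_config(n_dyads=2000)
        cfg.missingness = synthetic.MissingnessConfig(
            logit_intercept=20.0, item_mcar_rate=0.1
        )
        frame, truth = synthetic.generate_dyads(cfg)
        cols = item_columns("conduct", "self")
        rate = frame[cols].isna().to_numpy().mean()
        assert 0.07 < rate < 0.13
        assert truth.item_mask is not None
        assert frame[cols].isna().to_numpy().sum() == truth.item_mask[cols].to_numpy().sum()

    def test_incomplete_units_blank_but_covariates_kept(self):
        cfg = tiny_config(n_dyads=3000, with_covariates=True)
        cfg.missingness = synthetic.MissingnessConfig(logit_intercept=0.5)
        frame, _ = synthetic.generate_dyads(cfg)
        inc = frame["complete"] == 0
        assert inc.any()
        assert frame.loc[inc, item_columns("conduct", "self")].isna().all().all()
        assert frame.loc[inc, "sex"].notna().all()


class TestCalibration:
    def test_degenerate_point_mass(self):
        p0, p2 = synthetic._ordinal_probs_from_moments(1.0, 0.0)
        assert p0 == pytest.approx(0.0) and p2 == pytest.approx(0.0)

    def test_infeasible_targets_raise(self):
        with pytest.raises(synthetic.CalibrationError):
            synthetic._ordinal_probs_from_moments(1.0, 5.0)

    @pytest.mark.parametrize("construct,reporter,item_pos,want_mean,want_sd", [
        ("conduct", "parent", 0, 0.40, 0.63),   # temper item
        ("emotion", "self", 1, 1.07, 0.77),     # worry item
    ])
    def test_published_targets_reproduced(self, construct, reporter, item_pos,
                                          want_mean, want_sd):
        ref = {
            (construct, "self"): reference_item_moments(construct, "self"),
            (construct, "parent"): reference_item_moments(construct, "parent"),
        }
        base = synthetic.default_config(
            n_dyads=50000, seed=17, constructs=(construct,), with_covariates=False
        )
        cfg = synthetic.calibrate_to_moments(ref, base=base)
        frame, _ = synthetic.generate_dyads(cfg)
        block = scored_item_frame(frame, construct, reporter)
        col = block.columns[item_pos]
        assert block[col].mean() == pytest.approx(want_mean, abs=0.05)
        assert block[col].std() == pytest.approx(want_sd, abs=0.05)
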