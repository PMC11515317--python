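"""Estimator backends: recovery, degenerate cases, invariances."""

import subprocess
import sys
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from sepmed.fit import (
    FitError,
    fit_glm_sequence,
    fit_lgm,
    fit_mixed,
    _lagged_frame,
)
from sepmed.model_spec import simulation_study_lgm_spec, simulation_study_mixed_spec
from sepmed.simulate import PanelData, ScenarioConfig, simulate_lgm, simulate_mixed


def _shuffle_subjects(panel, seed=0):
    rng = np.random.default_rng(seed)
    ids = panel.df["id"].unique()
    remap = dict(zip(ids, rng.permutation(ids)))
    df = panel.df.copy()
    df["id"] = df["id"].map(remap)
    return PanelData(df)


class TestGLMSequence:
    def test_intercept_only_bernoulli_mean(self):
        # half the mediator values are 1 -> fitted probability must be 0.5
        n = 40
        ids = np.arange(n)
        rng = np.random.default_rng(1)
        df = pd.DataFrame({
            "id": np.repeat(ids, 2),
            "wave": np.tile([1, 2], n),
            "x": np.repeat((ids // 2) % 2, 2),
            # exactly half the wave-1 mediator values are 1, within each arm
            "m": np.column_stack(
                [ids % 2, rng.integers(0, 2, n)]
            ).ravel().astype(float),
            "y": rng.standard_normal(2 * n),
        })
        models = fit_glm_sequence(
            PanelData(df), families=("binomial-logit", "gaussian-identity"),
            pooled=False,
        )
        coefs = models.mediator[0].coefs
        for x in (0.0, 1.0):
            p = 1 / (1 + np.exp(-(coefs["const"] + coefs["x"] * x)))
            assert p == pytest.approx(0.5, abs=1e-6)

    def test_recovers_coefficients_without_random_effects(self):
        spec = simulation_study_mixed_spec(phi=np.zeros((4, 4)))
        panel = simulate_mixed(
            spec, ScenarioConfig(mechanism="mixed", n=5000, T=5, seed=21)
        )
        models = fit_glm_sequence(panel)
        wm, wy = models.mediator[0], models.outcome[0]
        # sampling SEs at n=5000, unit residual variance
        assert abs(wm.coefs["x"] - 0.5) < 3 * 0.032
        assert abs(wy.coefs["m"] - 0.2) < 3 * 0.01
        assert abs(wy.coefs["y_lag"] - 0.34) < 3 * 0.01
        assert wm.scale == pytest.approx(1.0, abs=0.05)

    def test_gamma_log_means_positive(self):
        spec = simulation_study_mixed_spec(
            phi=np.zeros((4, 4)), family_y="gamma-log",
            gamma0=0.2, gamma_m=0.05, gamma_lag_m=0.02, gamma_lag_y=0.05,
            sigma_eps_y=0.3,
        )
        panel = simulate_mixed(
            spec, ScenarioConfig(mechanism="mixed", n=500, T=3, seed=22)
        )
        models = fit_glm_sequence(
            panel, families=("gaussian-identity", "gamma-log")
        )
        df = _lagged_frame(panel)
        lin = models.outcome[0].coefs
        mu = np.exp(
            lin["const"] + lin["x"] * df["x"] + lin["m"] * df["m"]
            + lin["m_lag"] * df["m_lag"] + lin["y_lag"] * df["y_lag"]
        )
        assert (mu > 0).all()

    def test_stratified_wave1_has_no_lag_terms(self, small_mixed_panel):
        models = fit_glm_sequence(small_mixed_panel, pooled=False)
        assert "m_lag" not in models.mediator[0].coefs
        assert "y_lag" not in models.outcome[0].coefs
        assert "m_lag" in models.mediator[1].coefs

    def test_subject_relabelling_leaves_estimates_unchanged(self, small_mixed_panel):
        a = fit_glm_sequence(small_mixed_panel)
        b = fit_glm_sequence(_shuffle_subjects(small_mixed_panel))
        for k, v in a.mediator[0].coefs.items():
            assert b.mediator[0].coefs[k] == pytest.approx(v, abs=1e-9)


class TestMixedBackend:
    def test_near_deterministic_panel_recovers_coefficients(self):
        spec = simulation_study_mixed_spec(
            phi=0.25 * np.eye(4), sigma_eps_m=0.01, sigma_eps_y=0.01
        )
        panel = simulate_mixed(
            spec, ScenarioConfig(mechanism="mixed", n=800, T=4, seed=23)
        )
        fitted = fit_mixed(panel).spec
        assert fitted.beta_x == pytest.approx(0.5, abs=0.08)
        assert fitted.gamma_m == pytest.approx(0.2, abs=0.08)
        assert fitted.sigma_eps_y == pytest.approx(0.01, abs=0.01)

    def test_recovery_under_study_design(self, mixed_spec):
        panel = simulate_mixed(
            mixed_spec, ScenarioConfig(mechanism="mixed", n=2000, T=5, seed=24)
        )
        fitted = fit_mixed(panel)
        s = fitted.spec
        assert fitted.converged
        # 3-sigma bands from pilot replications of this design at n=2000
        assert s.beta_x == pytest.approx(0.5, abs=3 * 0.062)
        assert s.gamma_x == pytest.approx(0.7, abs=3 * 0.068)
        assert s.gamma_m == pytest.approx(0.2, abs=3 * 0.025)
        assert s.gamma_lag_y == pytest.approx(0.34, abs=3 * 0.008)
        assert s.phi[2, 2] == pytest.approx(1.0, abs=0.25)  # Var(gM)

    def test_agrees_with_lme4_reference(self, mixed_spec):
        """Cross-check both equations against an independent ML implementation."""
        panel = simulate_mixed(
            mixed_spec, ScenarioConfig(mechanism="mixed", n=300, T=4, seed=25)
        )
        ours = fit_mixed(panel).spec
        with tempfile.TemporaryDirectory() as tmp:
            csv = Path(tmp) / "panel.csv"
            _lagged_frame(panel).to_csv(csv, index=False)
            script = Path(tmp) / "fit.R"
            script.write_text(
                "suppressMessages(library(lme4))\n"
                f"d <- read.csv('{csv}')\n"
                "m1 <- lmer(m ~ x + m_lag + y_lag + (1|id), data=d, REML=FALSE)\n"
                "m2 <- lmer(y ~ x + m + m_lag + y_lag + (1 + m + m_lag || id),"
                " data=d, REML=FALSE)\n"
                "cat(c(fixef(m1), fixef(m2)), sep=',')\n"
            )
            out = subprocess.run(
                ["Rscript", str(script)], capture_output=True, text=True, check=True
            )
        vals = np.array([float(v) for v in out.stdout.strip().split(",")])
        ref_m, ref_y = vals[:4], vals[4:]
        np.testing.assert_allclose(
            [ours.beta0, ours.beta_x, ours.beta_lag_m, ours.beta_lag_y],
            ref_m, atol=2e-3,
        )
        np.testing.assert_allclose(
            [ours.gamma0, ours.gamma_x, ours.gamma_m, ours.gamma_lag_m,
             ours.gamma_lag_y],
            ref_y, atol=5e-3,
        )


class TestLGMBackend:
    def test_recovery_under_study_design(self, lgm_spec):
        panel = simulate_lgm(
            lgm_spec, ScenarioConfig(mechanism="lgm", n=5000, T=5, seed=26)
        )
        fitted = fit_lgm(panel)
        assert fitted.converged
        s = fitted.spec
        # 3-sigma bands ~ 3*sqrt(c/n) for unit-variance latents
        assert s.gamma12 == pytest.approx(0.44, abs=0.12)
        assert s.beta01 == pytest.approx(0.16, abs=0.10)
        assert s.gamma11 == pytest.approx(0.27, abs=0.12)
        assert s.gamma13 == pytest.approx(0.19, abs=0.10)
        np.testing.assert_allclose(s.zeta_sd, 1.0, atol=0.12)

    def test_low_noise_panel_recovers_structure_sharply(self):
        spec = simulation_study_lgm_spec(eps_sd_m=0.05, eps_sd_y=0.05)
        panel = simulate_lgm(
            spec, ScenarioConfig(mechanism="lgm", n=3000, T=5, seed=27)
        )
        s = fit_lgm(panel).spec
        assert s.gamma12 == pytest.approx(0.44, abs=0.06)
        assert s.eps_sd_y == pytest.approx(0.05, abs=0.02)

    def test_implied_moments_match_sample_moments_at_optimum(self, small_lgm_panel):
        from sepmed.fit import _group_stats

        fitted = fit_lgm(small_lgm_panel)
        stats = _group_stats(small_lgm_panel)
        Sigma = fitted.implied_cov
        d = np.diag(Sigma)
        for g in (0, 1):
            ng, mean, S = stats[g]
            mu = fitted.implied_mean[g]
            mean_se = np.sqrt(d / ng)
            assert np.all(np.abs(mean - mu) < 4 * mean_se)
            cov_se = np.sqrt((np.outer(d, d) + Sigma**2) / ng)
            assert np.all(np.abs(S - Sigma) < 5 * cov_se)

    def test_omitted_intercept_path_hits_regression_limits(self):
        # omitted-variable limits: gamma11 -> gamma11 + gamma12*beta01,
        # gamma13 -> gamma13 (eta0M and eta1M independent given X)
        spec = simulation_study_lgm_spec()
        panel = simulate_lgm(
            spec, ScenarioConfig(mechanism="lgm", n=30_000, T=5, seed=28)
        )
        fitted = fit_lgm(panel, include_intercept_path=False)
        assert fitted.spec.gamma12 == 0.0
        assert fitted.spec.gamma11 == pytest.approx(0.3404, abs=0.03)
        assert fitted.spec.gamma13 == pytest.approx(0.19, abs=0.04)
        # the free disturbance covariance absorbs gamma12 * Var(eta0M)
        assert fitted.psi_intercept_slope == pytest.approx(0.44, abs=0.06)

    def test_subject_order_invariance(self, small_lgm_panel):
        a = fit_lgm(small_lgm_panel).spec
        b = fit_lgm(_shuffle_subjects(small_lgm_panel, seed=3)).spec
        assert b.gamma12 == pytest.approx(a.gamma12, abs=1e-4)
        assert b.beta11 == pytest.approx(a.beta11, abs=1e-4)

    def test_loading_length_mismatch_rejected(self, small_lgm_panel):
        with pytest.raises(Exception):
            fit_lgm(small_lgm_panel, lam=np.arange(3.0))


class TestFittedSerialisation:
    def test_json_round_trip_preserves_gformula_output(self, small_mixed_panel,
                                                       small_lgm_panel):
        import json
        import warnings

        from sepmed.fit import fitted_from_dict, fitted_to_dict
        from sepmed.gformula import EstimatorConfig, gformula_mean
        from sepmed.model_spec import Intervention

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            cfg = EstimatorConfig(S=2000, B=0, seed=5)
        iv = Intervention(x_m=0, x_y=1)
        for fitted in (
            fit_glm_sequence(small_mixed_panel),
            fit_lgm(small_lgm_panel),
        ):
            blob = json.dumps(fitted_to_dict(fitted))
            back = fitted_from_dict(json.loads(blob))
            a = gformula_mean(fitted, iv, cfg, seed=1)
            b = gformula_mean(back, iv, cfg, seed=1)
            np.testing.assert_allclose(a, b, atol=1e-12)
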