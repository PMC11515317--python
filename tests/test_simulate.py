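"""Panel generators: shape contracts, determinism, moment convergence."""

import numpy as np
import pytest

from sepmed.fit import _lgm_implied
from sepmed.model_spec import simulation_study_lgm_spec, simulation_study_mixed_spec
from sepmed.simulate import PanelData, ScenarioConfig, simulate_lgm, simulate_mixed


class TestShapeContracts:
    def test_mixed_panel_is_balanced(self, mixed_spec):
        panel = simulate_mixed(
            mixed_spec, ScenarioConfig(mechanism="mixed", n=4, T=2, seed=1)
        )
        assert len(panel.df) == 8
        assert panel.n_subjects == 4 and panel.n_waves == 2
        assert (panel.df.groupby("id")["x"].nunique() == 1).all()

    def test_lgm_panel_has_one_row_per_wave(self, lgm_spec):
        panel = simulate_lgm(
            lgm_spec, ScenarioConfig(mechanism="lgm", n=7, T=5, seed=2)
        )
        assert (panel.df.groupby("id")["wave"].size() == 5).all()

    def test_seed_reproducibility(self, mixed_spec, lgm_spec):
        for sim, spec, mech in (
            (simulate_mixed, mixed_spec, "mixed"),
            (simulate_lgm, lgm_spec, "lgm"),
        ):
            scn = ScenarioConfig(mechanism=mech, n=50, T=5, seed=33)
            a = sim(spec, scn).df
            b = sim(spec, scn).df
            assert a.equals(b)

    def test_seed_is_mandatory(self):
        with pytest.raises(ValueError, match="seed"):
            ScenarioConfig(mechanism="mixed", n=10, T=2)

    def test_mechanism_mismatch_rejected(self, mixed_spec):
        with pytest.raises(ValueError):
            simulate_mixed(
                mixed_spec, ScenarioConfig(mechanism="lgm", n=10, T=5, seed=1)
            )


class TestDegenerateNoise:
    def test_mixed_zero_noise_follows_deterministic_recursion(self):
        spec = simulation_study_mixed_spec(
            phi=np.zeros((4, 4)), sigma_eps_m=1e-300, sigma_eps_y=1e-300, beta_x=0.0
        )
        panel = simulate_mixed(
            spec, ScenarioConfig(mechanism="mixed", n=20, T=3, seed=3)
        )
        m = panel.wide("m")
        y = panel.wide("y")
        x = panel.exposure
        m_exp = np.full(20, spec.beta0)
        y_exp = spec.gamma0 + spec.gamma_x * x + spec.gamma_m * m_exp
        for t in range(3):
            if t > 0:
                m_exp = (
                    spec.beta0
                    + spec.beta_lag_m * m[:, t - 1]
                    + spec.beta_lag_y * y[:, t - 1]
                )
                y_exp = (
                    spec.gamma0 + spec.gamma_x * x + spec.gamma_m * m_exp
                    + spec.gamma_lag_m * m[:, t - 1] + spec.gamma_lag_y * y[:, t - 1]
                )
            np.testing.assert_allclose(m[:, t], m_exp, atol=1e-10)
            np.testing.assert_allclose(y[:, t], y_exp, atol=1e-10)

    def test_lgm_zero_noise_is_exact_path_composition(self):
        spec = simulation_study_lgm_spec(zeta_sd=np.zeros(4), eps_sd_m=0.0, eps_sd_y=0.0)
        panel = simulate_lgm(spec, ScenarioConfig(mechanism="lgm", n=30, T=5, seed=4))
        y = panel.wide("y")[panel.exposure == 0]
        expected = spec.gamma00 + spec.lam * (
            spec.gamma10 + spec.gamma12 * spec.beta00 + spec.gamma13 * spec.beta10
        )
        np.testing.assert_allclose(y, np.broadcast_to(expected, y.shape), atol=1e-12)

    def test_wave1_outcome_mean_free_of_mediator_latents(self, lgm_spec):
        # lambda_1 = 0, so Y_1 loads only on eta0Y, which has no mediator terms
        panel = simulate_lgm(
            lgm_spec, ScenarioConfig(mechanism="lgm", n=50_000, T=5, seed=5)
        )
        y1 = panel.wide("y")[:, 0]
        x = panel.exposure
        for g, mu in ((0, lgm_spec.gamma00), (1, lgm_spec.gamma00 + lgm_spec.gamma01)):
            se = y1[x == g].std() / np.sqrt((x == g).sum())
            assert abs(y1[x == g].mean() - mu) < 3 * se


class TestMomentConvergence:
    def test_mixed_wave1_mediator_mean_under_treatment(self, mixed_spec):
        panel = simulate_mixed(
            mixed_spec, ScenarioConfig(mechanism="mixed", n=200_000, T=2, seed=6)
        )
        m1 = panel.wide("m")[:, 0]
        treated = panel.exposure == 1
        assert abs(m1[treated].mean() - 1.8) < 0.02  # beta0 + beta_x

    def test_lgm_slope_mean_under_treatment(self, lgm_spec):
        panel = simulate_lgm(
            lgm_spec, ScenarioConfig(mechanism="lgm", n=200_000, T=5, seed=7)
        )
        m = panel.wide("m")[panel.exposure == 1]
        lam = lgm_spec.lam
        D = np.column_stack([np.ones_like(lam), lam])
        H = np.linalg.solve(D.T @ D, D.T)
        slopes = m @ H.T[:, 1]
        assert abs(slopes.mean() - 1.17) < 0.02  # beta10 + beta11

    def test_exposure_frequency_near_half(self, mixed_spec):
        panel = simulate_mixed(
            mixed_spec, ScenarioConfig(mechanism="mixed", n=100_000, T=2, seed=8)
        )
        p = panel.exposure.mean()
        assert abs(p - 0.5) < 3 * 0.5 / np.sqrt(100_000)

    def test_lgm_panel_matches_implied_moments(self, lgm_spec):
        # generator vs the independent implied-moment calculator
        panel = simulate_lgm(
            lgm_spec, ScenarioConfig(mechanism="lgm", n=100_000, T=5, seed=9)
        )
        theta = np.array(
            [lgm_spec.beta00, lgm_spec.beta01, lgm_spec.beta10, lgm_spec.beta11,
             lgm_spec.gamma00, lgm_spec.gamma01, lgm_spec.gamma10, lgm_spec.gamma11,
             lgm_spec.gamma12, lgm_spec.gamma13,
             0.0, 0.0, 0.0, 0.0, 0.0, 0.0]
        )
        mu0, mu1, Sigma = _lgm_implied(theta, lgm_spec.lam, include_path=True)
        Z = np.hstack([panel.wide("m"), panel.wide("y")])
        x = panel.exposure
        for g, mu in ((0, mu0), (1, mu1)):
            Zg = Z[x == g]
            ng = len(Zg)
            se = Zg.std(axis=0) / np.sqrt(ng)
            assert np.all(np.abs(Zg.mean(axis=0) - mu) < 4 * se)
            emp_cov = np.cov(Zg.T)
            # per-entry Monte-Carlo SE of a Gaussian covariance estimate
            d = np.diag(Sigma)
            cov_se = np.sqrt((np.outer(d, d) + Sigma**2) / ng)
            assert np.all(np.abs(emp_cov - Sigma) < 5 * cov_se)


class TestConfounding:
    def test_mixed_confounder_hits_wave1_only(self, mixed_spec):
        scn = dict(mechanism="mixed", n=150_000, T=3, seed=10)
        base = simulate_mixed(mixed_spec, ScenarioConfig(**scn))
        conf = simulate_mixed(
            mixed_spec, ScenarioConfig(confounded=True, u_effect=2.0, **scn)
        )
        v_base = base.wide("m").var(axis=0)
        v_conf = conf.wide("m").var(axis=0)
        assert v_conf[0] - v_base[0] > 3.0  # +u_effect^2 * u_sd^2 at wave 1
        # induced extra covariance between M1 and Y1
        c_base = np.cov(base.wide("m")[:, 0], base.wide("y")[:, 0])[0, 1]
        c_conf = np.cov(conf.wide("m")[:, 0], conf.wide("y")[:, 0])[0, 1]
        assert c_conf - c_base > 2.0


class TestPanelValidation:
    def test_unbalanced_panel_rejected(self, small_mixed_panel):
        df = small_mixed_panel.df.iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced"):
            PanelData(df)

    def test_varying_exposure_rejected(self, small_mixed_panel):
        df = small_mixed_panel.df.copy()
        df.loc[0, "x"] = 1 - df.loc[0, "x"]
        with pytest.raises(ValueError, match="constant"):
            PanelData(df)
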