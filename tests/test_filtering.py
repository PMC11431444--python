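import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from brokenduet import (
    FilterSettings,
    HierarchicalModelSpec,
    PrecisionConfig,
    build_listener_model,
    filter_percept,
    free_energy,
    prediction_errors,
)
from brokenduet.filtering import FilterInstabilityError, initial_posterior

from linear_oracle import (
    generalized_filter_linear,
    kalman_smooth,
    random_linear_system,
    simulate_linear,
)


def _static_cause_spec(prior_mean=0.4, prior_lp=0.5, ext_lp=1.0):
    """Scalar decaying state observed directly; cause observed too."""
    return HierarchicalModelSpec(
        f=lambda x, v: -0.1 * x,
        g=lambda x, v: np.array([x[0] + v[0]]),
        state_dim=1,
        obs_dim=1,
        cause_dim=1,
        internal_log_precision=1.0,
        external_log_precision=ext_lp,
        cause_prior_mean=(prior_mean,),
        cause_prior_log_precision=prior_lp,
        fx=lambda x, v: np.array([[-0.1]]),
        fv=lambda x, v: np.array([[0.0]]),
        gx=lambda x, v: np.array([[1.0]]),
        gv=lambda x, v: np.array([[1.0]]),
    )


class TestPredictionErrors:
    def test_weighting_identity(self, listener_spec_a):
        """Weighted errors are exactly precision times raw errors."""
        from brokenduet.filtering import _Geometry

        spec = listener_spec_a
        geo = _Geometry(spec)
        rng = np.random.default_rng(3)
        mu = rng.normal(size=spec.n_mu)
        y = rng.normal(size=spec.state_order)
        e = prediction_errors(spec, mu, y)
        assert np.allclose(e["outcome_weighted"], geo.Pi_v @ e["outcome_raw"])
        assert np.allclose(e["dynamics_weighted"], geo.Pi_x @ e["dynamics_raw"])
        assert np.allclose(e["cause_weighted"], geo.Pi_eta @ e["cause_raw"])

    def test_zero_cause_error_at_prior_mean(self, listener_spec_a):
        spec = listener_spec_a
        mu = initial_posterior(spec, (-0.8, 3.0, 0.0))
        y = np.zeros(spec.state_order)
        e = prediction_errors(spec, mu, y)
        assert np.allclose(e["cause_raw"], 0.0)

    def test_external_precision_scales_weighted_outcome_only(self):
        rng = np.random.default_rng(1)
        delta = 1.5
        spec0 = _static_cause_spec(ext_lp=0.0)
        spec1 = _static_cause_spec(ext_lp=delta)
        mu = rng.normal(size=spec0.n_mu)
        y = rng.normal(size=spec0.state_order)
        e0 = prediction_errors(spec0, mu, y)
        e1 = prediction_errors(spec1, mu, y)
        assert np.allclose(e1["outcome_raw"], e0["outcome_raw"])
        assert np.allclose(
            e1["outcome_weighted"], np.exp(delta) * e0["outcome_weighted"]
        )


class TestFreeEnergy:
    def test_zero_errors_hit_logdet_floor(self, listener_spec_a):
        """With all errors zero, F equals its error-independent floor."""
        from brokenduet.filtering import _Geometry

        spec = listener_spec_a
        geo = _Geometry(spec)
        floor = -0.5 * geo.logdet
        # construct a zero-error configuration: origin state (a fixed
        # point), cause at prior mean with zero higher orders, zero data
        mu = np.zeros(spec.n_mu)
        mu[spec.n_state] = 1.0  # cause prior mean
        y = np.zeros(spec.state_order)
        # outcome error is zero because g(0, 1) = 0
        assert free_energy(spec, mu, y) == pytest.approx(floor)

    def test_quadratic_scaling(self):
        spec = _static_cause_spec()
        rng = np.random.default_rng(2)
        mu = rng.normal(size=spec.n_mu)
        y = rng.normal(size=spec.state_order)
        from brokenduet.filtering import _Geometry

        geo = _Geometry(spec)
        (e_v, e_x, e_eta), _ = geo.errors(mu, y)
        quad = e_v @ geo.Pi_v @ e_v
        # doubling the raw outcome error at fixed precisions quadruples
        # its quadratic contribution
        assert 0.5 * (2 * e_v) @ geo.Pi_v @ (2 * e_v) == pytest.approx(
            4 * 0.5 * quad
        )

    def test_minimiser_matches_conjugate_gaussian_posterior(self):
        """The free-energy minimum over a static scalar cause is the
        precision-weighted blend of prior and observation."""
        prior_mean, prior_lp, ext_lp = 0.4, 0.5, 1.0
        spec = _static_cause_spec(prior_mean, prior_lp, ext_lp)
        from brokenduet.filtering import _Geometry

        geo = _Geometry(spec)
        y_obs = 1.7
        y_gen = np.zeros(spec.state_order)
        y_gen[0] = y_obs

        def f_of_v(v):
            mu = np.zeros(spec.n_mu)
            mu[spec.n_state] = v
            return free_energy(spec, mu, y_gen)

        found = minimize_scalar(f_of_v, bounds=(-5, 5), method="bounded").x
        w_obs = geo.Pi_v[0, 0]
        w_prior = geo.Pi_eta[0, 0]
        expected = (w_obs * y_obs + w_prior * prior_mean) / (w_obs + w_prior)
        assert found == pytest.approx(expected, abs=1e-4)


class TestFilter:
    def test_noiseless_linear_tracking(self):
        """Exact data from the model itself is tracked to high accuracy."""
        w = 0.2
        A = np.array([[0.0, -w], [w, 0.0]])
        from scipy.linalg import expm

        F = expm(A)
        N = 200
        X = np.empty((N, 2))
        x = np.array([1.0, 0.0])
        for i in range(N):
            X[i] = x
            x = F @ x
        spec = HierarchicalModelSpec(
            f=lambda x_, v_: A @ x_,
            g=lambda x_, v_: x_,
            state_dim=2,
            obs_dim=2,
            cause_dim=0,
            internal_log_precision=6.0,
            external_log_precision=6.0,
            fx=lambda x_, v_: A,
            gx=lambda x_, v_: np.eye(2),
        )
        post = filter_percept(
            spec, X, init_state=X[0], settings=FilterSettings(rate=1.0)
        )
        err = np.linalg.norm(post.state_means[5:-5] - X[5:-5], axis=1)
        assert err.max() < 1e-2

    def test_kalman_smoother_agreement_single_system(self):
        rng = np.random.default_rng(123)
        A, C = random_linear_system(rng, 2)
        X, Y = simulate_linear(rng, A, C, 300)
        xs = kalman_smooth(A, C, Y, X[0])
        gf = generalized_filter_linear(A, C, Y, X[0])
        sl = slice(20, 280)
        rel = np.sqrt(np.mean((gf[sl] - xs[sl]) ** 2)) / X[sl].std()
        assert rel < 0.05

    def test_uninformative_data_leaves_cause_at_prior(self):
        """With the observation blind to the cause, the posterior cause
        stays at its prior mean."""
        spec = HierarchicalModelSpec(
            f=lambda x, v: -0.1 * x,
            g=lambda x, v: np.array([x[0]]),
            state_dim=1,
            obs_dim=1,
            cause_dim=1,
            internal_log_precision=1.0,
            external_log_precision=1.0,
            cause_prior_mean=(0.7,),
            cause_prior_log_precision=0.0,
            fx=lambda x, v: np.array([[-0.1]]),
            fv=lambda x, v: np.array([[0.0]]),
            gx=lambda x, v: np.array([[1.0]]),
            gv=lambda x, v: np.array([[0.0]]),
        )
        y = np.exp(-0.1 * np.arange(100.0))
        post = filter_percept(spec, y, init_state=[1.0])
        assert np.allclose(post.cause_means[:, 0], 0.7, atol=1e-8)

    def test_self_inversion_consistency(
        self, broken_trajectory, matched_percept
    ):
        """A percept generated by the listener's own model, inverted from
        the matching initial state, is tracked to a small residual."""
        spec = build_listener_model(PrecisionConfig(0.0, 4.0))
        post = filter_percept(spec, matched_percept, init_state=(0.8, -3, 0))
        resid = matched_percept[200:] - post.predicted_obs[200:, 0]
        assert np.mean(resid**2) < 0.01 * np.var(matched_percept)

    def test_determinism(self, matched_percept, listener_spec_a):
        y = matched_percept[:128]
        a = filter_percept(listener_spec_a, y, init_state=(0.8, -3, 0))
        b = filter_percept(listener_spec_a, y, init_state=(0.8, -3, 0))
        assert np.array_equal(a.generalized_means, b.generalized_means)
        assert np.array_equal(a.free_energy, b.free_energy)

    def test_instability_reports_sample(self, listener_spec_a):
        y = np.zeros(50)
        with pytest.raises(FilterInstabilityError) as exc:
            filter_percept(
                listener_spec_a,
                y,
                init_state=(0.8, -3, 0),
                settings=FilterSettings(instability_bound=1e-6),
            )
        assert exc.value.sample >= 0

    def test_empty_percept_rejected(self, listener_spec_a):
        with pytest.raises(ValueError):
            filter_percept(listener_spec_a, np.empty(0))

    def test_free_energy_descends_on_static_data(self, listener_spec_a):
        """On a constant percept the assimilation flow settles into a
        free-energy minimum: large initial descent, then a flat plateau
        with only tiny numerical wiggles."""
        y = np.full(200, 1.3)
        post = filter_percept(listener_spec_a, y, init_state=(-0.8, 3, 0))
        fe = post.free_energy_trace
        steps = np.diff(fe, axis=1).ravel()
        assert np.mean(steps > 1e-5) == 0.0
        assert fe[-1, -1] < fe[0, 0]
        assert np.ptp(post.free_energy[-50:]) < 1e-4

    def test_per_sample_net_descent_on_dynamic_data(
        self, matched_percept, listener_spec_a
    ):
        """Within each sample's inner iterations the net free-energy
        change is a descent for almost every sample."""
        post = filter_percept(
            listener_spec_a, matched_percept[:512], init_state=(0.8, -3, 0)
        )
        fe = post.free_energy_trace
        net = fe[:, -1] - fe[:, 0]
        assert np.mean(net > 1e-6) <= 0.01
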