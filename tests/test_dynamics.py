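import numpy as np
import pytest
from hypothesis import given, strategies as st

from brokenduet import (
    DivergenceError,
    LorenzParameters,
    integrate,
    lobe_sign,
    lorenz_flow,
)
from brokenduet.dynamics import InvalidStateError, integrate_batch, lorenz_jacobian

finite = st.floats(-50, 50, allow_nan=False)
param_st = st.builds(
    LorenzParameters,
    sigma=st.floats(-20, 20),
    r=st.floats(-30, 30),
    b=st.floats(-5, 5),
)


class TestFlow:
    def test_broken_constructor_values(self):
        p = LorenzParameters.broken()
        assert (p.sigma, p.r, p.b) == (0.12, 0.0, -0.6)

    @pytest.mark.parametrize(
        "state,params,expected",
        [
            ((0, 0, 0), LorenzParameters.classical(), (0, 0, 0)),
            ((0, 0, 0), LorenzParameters.broken(), (0, 0, 0)),
            ((1, 1, 1), LorenzParameters(10, 28, 8 / 3), (0, 26, -5 / 3)),
        ],
    )
    def test_flow_values(self, state, params, expected):
        assert lorenz_flow(state, params) == pytest.approx(expected)

    @given(x=finite, y=finite, z=finite, params=param_st)
    def test_mirror_equivariance(self, x, y, z, params):
        """Negating (x, y) negates (x', y') and preserves z' exactly."""
        f = lorenz_flow((x, y, z), params)
        g = lorenz_flow((-x, -y, z), params)
        assert g[0] == -f[0] and g[1] == -f[1] and g[2] == f[2]

    def test_jacobian_matches_finite_differences(self):
        p = LorenzParameters.broken()
        s = np.array([0.7, -2.0, 1.3])
        J = lorenz_jacobian(s, p)
        eps = 1e-7
        for k in range(3):
            d = np.zeros(3)
            d[k] = eps
            num = (lorenz_flow(s + d, p) - lorenz_flow(s - d, p)) / (2 * eps)
            assert np.allclose(J[:, k], num, atol=1e-5)

    def test_non_finite_state_rejected(self):
        with pytest.raises(InvalidStateError):
            lorenz_flow((np.nan, 0, 0), LorenzParameters.broken())


class TestIntegrate:
    def test_origin_is_fixed_point(self, broken_params):
        traj = integrate((0, 0, 0), broken_params, n_steps=10)
        assert np.all(traj.states == 0)

    def test_length_and_start(self, broken_params):
        traj = integrate((0.8, -3, 0), broken_params, n_steps=50)
        assert len(traj) == 51
        assert traj.states[0] == pytest.approx([0.8, -3, 0])

    def test_deterministic(self, broken_params):
        a = integrate((0.8, -3, 0), broken_params, n_steps=200)
        b = integrate((0.8, -3, 0), broken_params, n_steps=200)
        assert np.array_equal(a.states, b.states)

    def test_lobe_confinement(self, broken_trajectory):
        """Broken-regime trajectories never leave their starting lobe."""
        assert np.all(broken_trajectory.x > 0)

    def test_mirrored_trajectory_equality(self, broken_params):
        a = integrate((0.8, -3, 0.5), broken_params, n_steps=1000)
        b = integrate((-0.8, 3, 0.5), broken_params, n_steps=1000)
        flip = np.array([-1.0, -1.0, 1.0])
        assert np.allclose(a.states * flip, b.states, atol=1e-9)

    def test_divergence_raises_with_step(self):
        p = LorenzParameters.classical()
        with pytest.raises(DivergenceError) as exc:
            # huge dt makes RK4 blow up quickly
            integrate((1, 1, 20), p, n_steps=100, dt=10.0, substeps=1)
        assert exc.value.step >= 1

    def test_convergence_order(self, broken_params):
        """Halving the step scales the endpoint error about as RK4's 4th
        order.  The horizon is kept to one orbit (10 samples) because
        chaotic sensitivity saturates endpoint errors on longer runs."""
        ref = integrate(
            (0.8, -3, 0), broken_params, n_steps=10, substeps=64
        ).states[-1]
        e1 = np.linalg.norm(
            integrate((0.8, -3, 0), broken_params, 10, substeps=2).states[-1]
            - ref
        )
        e2 = np.linalg.norm(
            integrate((0.8, -3, 0), broken_params, 10, substeps=4).states[-1]
            - ref
        )
        ratio = e1 / e2
        assert 2**4 / 2 < ratio < 2**4 * 2

    def test_local_linearization_matches_rk4(self, broken_params):
        # short horizon and fine steps: local linearization is lower order
        # than RK4 and chaos amplifies any gap on long runs
        a = integrate((0.8, -3, 0), broken_params, 20, substeps=32)
        b = integrate(
            (0.8, -3, 0), broken_params, 20, method="local_linear", substeps=16
        )
        assert np.allclose(a.states, b.states, atol=5e-2)

    def test_batch_agrees_with_scalar(self, broken_params):
        inits = np.array([[0.8, -3, 0], [-0.8, 3, 0]])
        batch = integrate_batch(inits, broken_params, n_steps=100)
        for i, init in enumerate(inits):
            single = integrate(init, broken_params, n_steps=100)
            assert np.allclose(batch[i], single.states, atol=1e-12)


class TestLobeSign:
    @pytest.mark.parametrize(
        "state,expected",
        [((0.8, -3, 0), 1), ((-0.8, 3, 0), -1), ((0, 1, 1), 1)],
    )
    def test_examples(self, state, expected):
        assert lobe_sign(state) == expected

    def test_bistability_ensemble(self, broken_params):
        """Perturbed on-attractor starts with |x| >= 0.1 on each side stay
        in their lobe.  (Random far-field states are not used: the broken
        regime's attracting sets have thin basins and the far field
        diverges to infinity.)"""
        from brokenduet.dynamics import integrate

        rng = np.random.default_rng(0)
        base = integrate((0.8, -3, 0), broken_params, n_steps=2000).states
        picks = base[rng.integers(200, 2000, size=25)]
        inits = np.vstack([picks, picks * np.array([-1.0, -1.0, 1.0])])
        inits += rng.normal(0, 0.01, size=inits.shape)
        inits = inits[np.abs(inits[:, 0]) >= 0.1]
        states = integrate_batch(
            inits, broken_params, n_steps=2000, on_divergence="mask"
        )
        x = states[:, :, 0]
        escaped = np.any(np.isnan(x), axis=1)
        assert np.mean(escaped) < 0.2  # thin-basin escapes, not switches
        bounded = x[~escaped]
        signs = np.sign(bounded)
        assert np.all(signs == signs[:, :1])


class TestSerialization:
    def test_parameters_json_roundtrip(self):
        p = LorenzParameters.broken()
        assert LorenzParameters.from_json(p.to_json()) == p

    def test_trajectory_csv_roundtrip(self, tmp_path, broken_params):
        traj = integrate((0.8, -3, 0), broken_params, n_steps=20)
        path = tmp_path / "traj.csv"
        traj.to_csv(path)
        back = type(traj).from_csv(path)
        assert np.allclose(back.states, traj.states)
        assert np.allclose(back.times, traj.times)
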