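"""Synthetic linear-Gaussian systems and an independent Kalman-smoother oracle.

Used to validate the generalized-filtering engine against classical exact
inference.  The systems are lightly damped random rotations observed
through an orthogonal matrix, driven by small serially correlated
(analytic) Gaussian noise, so that both the generalized filter (which
assumes smooth noise) and the Kalman smoother (which assumes white noise)
operate close to their common exact-inference limit.
"""

import numpy as np
from scipy.linalg import expm, qr
from scipy.ndimage import gaussian_filter1d

from brokenduet.filtering import (
    FilterSettings,
    HierarchicalModelSpec,
    filter_percept,
)

#: Noise autocorrelation width matching the engine's default smoothness.
NOISE_WIDTH = 0.5
PROCESS_NOISE_SD = 0.0025
OBS_NOISE_SD = 0.01


def smooth_noise(rng, shape, sd, width=NOISE_WIDTH):
    w = rng.normal(size=shape)
    s = gaussian_filter1d(w, width, axis=0, mode="wrap")
    s *= sd / s.std(axis=0, keepdims=True)
    return s


def random_linear_system(rng, dim):
    """A stable rotation-like continuous system with orthogonal observation."""
    M = rng.normal(size=(dim, dim))
    A = 0.5 * (M - M.T) * 0.25 - 0.01 * np.eye(dim)
    C = qr(rng.normal(size=(dim, dim)))[0]
    return A, C


def simulate_linear(rng, A, C, n_samples, q=PROCESS_NOISE_SD, r=OBS_NOISE_SD):
    dim = A.shape[0]
    F = expm(A)
    x = rng.normal(size=dim)
    x /= max(np.linalg.norm(x) / np.sqrt(dim), 1e-9)
    pn = smooth_noise(rng, (n_samples, dim), q)
    on = smooth_noise(rng, (n_samples, dim), r)
    X = np.empty((n_samples, dim))
    Y = np.empty((n_samples, dim))
    for t in range(n_samples):
        X[t] = x
        Y[t] = C @ x + on[t]
        x = F @ x + pn[t]
    return X, Y


def kalman_smooth(A, C, Y, x0, q=PROCESS_NOISE_SD, r=OBS_NOISE_SD):
    """Classical RTS-smoothed state means via statsmodels (the oracle)."""
    from statsmodels.tsa.statespace.kalman_smoother import KalmanSmoother

    dim = A.shape[0]
    ks = KalmanSmoother(k_endog=dim, k_states=dim)
    ks.bind(np.asfortranarray(Y.T))
    ks["design"] = C
    ks["transition"] = expm(A)
    ks["selection"] = np.eye(dim)
    ks["state_cov"] = np.eye(dim) * q**2
    ks["obs_cov"] = np.eye(dim) * r**2
    ks.initialize_known(x0, np.eye(dim) * 1e-6)
    return ks.smooth().smoothed_state.T


def generalized_filter_linear(A, C, Y, x0, q=PROCESS_NOISE_SD, r=OBS_NOISE_SD):
    """Invert the same system with the generalized-filtering engine."""
    dim = A.shape[0]
    spec = HierarchicalModelSpec(
        f=lambda x, v: A @ x,
        g=lambda x, v: C @ x,
        state_dim=dim,
        obs_dim=dim,
        cause_dim=0,
        internal_log_precision=float(-2 * np.log(q)),
        external_log_precision=float(-2 * np.log(r)),
        fx=lambda x, v: A,
        gx=lambda x, v: C,
    )
    post = filter_percept(
        spec, Y, init_state=x0, settings=FilterSettings(rate=1.0)
    )
    return post.state_means


def smoother_agreement(rng, dim, n_samples=500):
    """RMS discrepancy between engine and oracle, relative to state sd."""
    A, C = random_linear_system(rng, dim)
    X, Y = simulate_linear(rng, A, C, n_samples)
    xs = kalman_smooth(A, C, Y, X[0])
    gf = generalized_filter_linear(A, C, Y, X[0])
    sl = slice(20, n_samples - 20)  # discard embedding boundary windows
    sd = X[sl].std()
    return float(np.sqrt(np.mean((gf[sl] - xs[sl]) ** 2)) / sd)
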