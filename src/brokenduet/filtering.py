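"""Generalized filtering of two-level hierarchical nonlinear state-space models.

The listener's inversion scheme: a variational (Laplace, modes-only)
posterior over generalized states and causes is assimilated sample by
sample by a predict-correct flow on the model's free energy

    F = 1/2 sum_streams  e' Pi e  - 1/2 sum log|Pi|  + const

with three error streams at each instant:

* outcome error      e_v = y~ - g~(mu)          (generalized percept)
* dynamics error     e_x = D mu~x - f~(mu)      (motion minus predicted flow)
* cause prior error  e_eta = mu~v - eta~        (static cause vs prior)

each weighted by its generalized precision.  Assimilation integrates the
generalized gradient flow  mu' = D mu - rate * dF/dmu  over each sample
interval with local-linearization sub-steps: the shift operator D carries
prediction, the free-energy gradient (precision-weighted prediction
errors) carries correction, and the Gauss-Newton curvature stabilises the
step.  The scheme is single-pass continuous data assimilation: no
backward smoothing sweep.  Because the observation embedding uses a
symmetric sample window, each posterior nevertheless reflects a short
horizon of future samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .gencoords import (
    SmoothnessModel,
    shift_operator,
    embedding_matrix,
    generalized_precision,
)
from .speaker import PerceptSeries

__all__ = [
    "HierarchicalModelSpec",
    "FilterSettings",
    "PosteriorTrajectory",
    "prediction_errors",
    "free_energy",
    "filter_percept",
    "FilterInstabilityError",
]


class FilterInstabilityError(RuntimeError):
    """Posterior flow blew up; raised with the offending sample index."""

    def __init__(self, sample: int, magnitude: float):
        self.sample = sample
        super().__init__(
            f"posterior flow diverged at sample {sample} "
            f"(|mu| ~ {magnitude:.3g}); consider a smaller correction step "
            "or more damping"
        )


def _numerical_jacobian(func, x0, out_dim, eps=1e-6):
    x0 = np.asarray(x0, dtype=float)
    J = np.empty((out_dim, len(x0)))
    f0 = np.asarray(func(x0), dtype=float)
    for k in range(len(x0)):
        xp = x0.copy()
        xp[k] += eps
        J[:, k] = (np.asarray(func(xp), dtype=float) - f0) / eps
    return J


@dataclass(frozen=True)
class HierarchicalModelSpec:
    """A (up to) two-level generative model for generalized filtering.

    Level 1 has ``state_dim`` hidden states with evolution map ``f`` and
    observation map ``g``, both functions of (states, causes); level 2 is
    a static cause of dimension ``cause_dim`` (0 disables the level) with
    a Gaussian prior.  Log-precisions: ``internal_log_precision`` weights
    the dynamics (state evolution) error, ``external_log_precision`` the
    outcome error, ``cause_prior_log_precision`` the cause prior error.
    States/outcomes are embedded to ``state_order`` generalized
    coordinates, causes to ``cause_order``.
    """

    f: Callable[[np.ndarray, np.ndarray], np.ndarray]
    g: Callable[[np.ndarray, np.ndarray], np.ndarray]
    state_dim: int
    obs_dim: int = 1
    cause_dim: int = 0
    internal_log_precision: float = 0.0
    external_log_precision: float = 0.0
    cause_prior_mean: tuple = ()
    cause_prior_log_precision: float = 0.0
    state_order: int = 6
    cause_order: int = 2
    smoothness: SmoothnessModel = field(default_factory=SmoothnessModel)
    fx: Callable | None = None
    fv: Callable | None = None
    gx: Callable | None = None
    gv: Callable | None = None

    def __post_init__(self):
        if self.state_dim < 1 or self.obs_dim < 1:
            raise ValueError("state_dim and obs_dim must be >= 1")
        if self.cause_dim < 0:
            raise ValueError("cause_dim must be >= 0")
        if self.state_order < 2:
            raise ValueError("state_order must be >= 2")
        if self.cause_dim and len(self.cause_prior_mean) != self.cause_dim:
            raise ValueError("cause_prior_mean length must equal cause_dim")
        for lp in (
            self.internal_log_precision,
            self.external_log_precision,
            self.cause_prior_log_precision,
        ):
            if not np.isfinite(lp):
                raise ValueError("log-precisions must be finite")

    # -- geometry helpers ---------------------------------------------------
    @property
    def n_state(self) -> int:
        return self.state_order * self.state_dim

    @property
    def n_cause(self) -> int:
        return self.cause_order * self.cause_dim

    @property
    def n_mu(self) -> int:
        return self.n_state + self.n_cause

    def split(self, mu: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Split a flat posterior vector into (orders, dim) state and cause blocks."""
        mu = np.asarray(mu, dtype=float)
        xs = mu[: self.n_state].reshape(self.state_order, self.state_dim)
        vs = mu[self.n_state :].reshape(
            self.cause_order if self.cause_dim else 0, max(self.cause_dim, 1)
        )
        if not self.cause_dim:
            vs = np.zeros((0, 0))
        return xs, vs

    def _jac(self, which: str, x0: np.ndarray, v0: np.ndarray) -> np.ndarray:
        f, g = self.f, self.g
        user = getattr(self, which)
        if user is not None:
            return np.atleast_2d(np.asarray(user(x0, v0), dtype=float))
        if which == "fx":
            return _numerical_jacobian(lambda x: f(x, v0), x0, self.state_dim)
        if which == "fv":
            return _numerical_jacobian(lambda v: f(x0, v), v0, self.state_dim)
        if which == "gx":
            return _numerical_jacobian(lambda x: g(x, v0), x0, self.obs_dim)
        if which == "gv":
            return _numerical_jacobian(lambda v: g(x0, v), v0, self.obs_dim)
        raise ValueError(which)


@dataclass(frozen=True)
class FilterSettings:
    """Numerical knobs of the assimilation loop.

    Each sample is assimilated by integrating the generalized gradient
    flow  mu' = D mu - rate * dF/dmu  over one sample interval in
    ``inner_iterations`` local-linearization sub-steps (the flow Jacobian
    D - rate * H, with H the Gauss-Newton curvature, stabilises each
    sub-step).  ``rate`` is the gradient-flow rate constant; the posterior
    magnitude is bounded by ``instability_bound``.
    """

    inner_iterations: int = 8
    rate: float = 16.0
    instability_bound: float = 1e6
    record_free_energy_trace: bool = True


@dataclass(frozen=True)
class PosteriorTrajectory:
    """Per-sample posterior means, prediction errors and free energy.

    Error arrays hold full generalized (order-major) error vectors per
    sample; the weighted arrays are the raw ones multiplied by the
    corresponding generalized precision matrices (an exact identity).
    ``free_energy_trace`` holds the inner-iteration free-energy values at
    every sample (shape (n_samples, inner_iterations + 1)), documenting
    the per-sample descent.
    """

    times: np.ndarray
    state_means: np.ndarray  # (N, state_dim) order-0 posterior means
    cause_means: np.ndarray  # (N, cause_dim)
    predicted_obs: np.ndarray  # (N, obs_dim)
    generalized_means: np.ndarray  # (N, n_mu) full posterior vector
    raw_outcome_error: np.ndarray  # (N, state_order*obs_dim)
    weighted_outcome_error: np.ndarray
    raw_dynamics_error: np.ndarray  # (N, state_order*state_dim)
    weighted_dynamics_error: np.ndarray
    raw_cause_error: np.ndarray  # (N, cause_order*cause_dim)
    weighted_cause_error: np.ndarray
    free_energy: np.ndarray  # (N,)
    free_energy_trace: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        cols = {"t": self.times}
        names = ["x", "y", "z"]
        for i in range(self.state_means.shape[1]):
            nm = names[i] if self.state_means.shape[1] == 3 else f"x{i}"
            cols[f"{nm}_post"] = self.state_means[:, i]
        for j in range(self.cause_means.shape[1]):
            cols[f"v1_post_{j}" if self.cause_means.shape[1] > 1 else "v1_post"] = (
                self.cause_means[:, j]
            )
        for j in range(self.predicted_obs.shape[1]):
            cols["v0_pred" if self.predicted_obs.shape[1] == 1 else f"v0_pred_{j}"] = (
                self.predicted_obs[:, j]
            )
        cols["outcome_error_w"] = self.weighted_outcome_error[:, 0]
        if self.raw_cause_error.shape[1]:
            cols["cause_error_w"] = self.weighted_cause_error[:, 0]
        cols["free_energy"] = self.free_energy
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# error / free-energy evaluation


class _Geometry:
    """Precomputed matrices shared across samples for one model spec."""

    def __init__(self, spec: HierarchicalModelSpec):
        self.spec = spec
        n, dx, dy = spec.state_order, spec.state_dim, spec.obs_dim
        d, dv = spec.cause_order, spec.cause_dim

        self.D_state = shift_operator(n, dx)
        self.D_cause = shift_operator(d, dv) if dv else np.zeros((0, 0))

        s_unit = SmoothnessModel(spec.smoothness.smoothness, 0.0)
        S_n = generalized_precision(s_unit, n)
        self.Pi_v = np.kron(S_n, np.eye(dy)) * np.exp(spec.external_log_precision)
        self.Pi_x = np.kron(S_n, np.eye(dx)) * np.exp(spec.internal_log_precision)
        if dv:
            S_d = generalized_precision(s_unit, d)
            self.Pi_eta = np.kron(S_d, np.eye(dv)) * np.exp(
                spec.cause_prior_log_precision
            )
            self.eta = np.zeros(d * dv)
            self.eta[:dv] = np.asarray(spec.cause_prior_mean, dtype=float)
        else:
            self.Pi_eta = np.zeros((0, 0))
            self.eta = np.zeros(0)

        # selector coupling cause orders into state/outcome orders
        self.sel = np.eye(n, d) if dv else np.zeros((n, 0))

        # log-determinant constants of the free energy
        self.logdet = 0.0
        for Pi in (self.Pi_v, self.Pi_x, self.Pi_eta):
            if Pi.size:
                self.logdet += np.linalg.slogdet(Pi)[1]

    def errors(self, mu: np.ndarray, y_gen: np.ndarray):
        """Raw generalized errors and their Jacobians at posterior mu."""
        spec = self.spec
        n, dx, dy = spec.state_order, spec.state_dim, spec.obs_dim
        d, dv = spec.cause_order, spec.cause_dim
        xs, vs = spec.split(mu)
        x0 = xs[0]
        v0 = vs[0] if dv else np.zeros(0)

        Jfx = spec._jac("fx", x0, v0)
        Jgx = spec._jac("gx", x0, v0)
        if dv:
            Jfv = spec._jac("fv", x0, v0)
            Jgv = spec._jac("gv", x0, v0)

        # generalized maps: order 0 exact, higher orders via the Jacobian
        f_gen = np.empty((n, dx))
        g_gen = np.empty((n, dy))
        f_gen[0] = np.asarray(spec.f(x0, v0), dtype=float)
        g_gen[0] = np.atleast_1d(np.asarray(spec.g(x0, v0), dtype=float))
        for i in range(1, n):
            vi = vs[i] if (dv and i < d) else np.zeros(dv)
            f_gen[i] = Jfx @ xs[i] + (Jfv @ vi if dv else 0.0)
            g_gen[i] = Jgx @ xs[i] + (Jgv @ vi if dv else 0.0)

        mu_x = mu[: spec.n_state]
        e_v = y_gen - g_gen.ravel()
        e_x = self.D_state @ mu_x - f_gen.ravel()
        e_eta = (mu[spec.n_state :] - self.eta) if dv else np.zeros(0)

        # Jacobians of the errors w.r.t. the flat posterior (order-major)
        J_v = np.zeros((n * dy, spec.n_mu))
        J_v[:, : spec.n_state] = -np.kron(np.eye(n), Jgx)
        J_x = np.zeros((n * dx, spec.n_mu))
        J_x[:, : spec.n_state] = self.D_state - np.kron(np.eye(n), Jfx)
        if dv:
            J_v[:, spec.n_state :] = -np.kron(self.sel, Jgv)
            J_x[:, spec.n_state :] = -np.kron(self.sel, Jfv)
            J_eta = np.zeros((d * dv, spec.n_mu))
            J_eta[:, spec.n_state :] = np.eye(d * dv)
        else:
            J_eta = np.zeros((0, spec.n_mu))
        return (e_v, e_x, e_eta), (J_v, J_x, J_eta)

    def free_energy(self, mu, y_gen, errors=None) -> float:
        if errors is None:
            errors, _ = self.errors(mu, y_gen)
        e_v, e_x, e_eta = errors
        quad = e_v @ self.Pi_v @ e_v + e_x @ self.Pi_x @ e_x
        if e_eta.size:
            quad += e_eta @ self.Pi_eta @ e_eta
        return 0.5 * (quad - self.logdet)


def prediction_errors(
    spec: HierarchicalModelSpec, mu: np.ndarray, y_gen: np.ndarray
) -> dict:
    """Raw and precision-weighted generalized errors at a posterior point.

    ``mu`` is the flat order-major posterior (states then causes);
    ``y_gen`` the generalized observation.  Weighted errors are the raw
    ones multiplied by the corresponding generalized precisions.
    """
    geo = _Geometry(spec)
    (e_v, e_x, e_eta), _ = geo.errors(np.asarray(mu, dtype=float), y_gen)
    return {
        "outcome_raw": e_v,
        "outcome_weighted": geo.Pi_v @ e_v,
        "dynamics_raw": e_x,
        "dynamics_weighted": geo.Pi_x @ e_x,
        "cause_raw": e_eta,
        "cause_weighted": geo.Pi_eta @ e_eta if e_eta.size else e_eta,
    }


def free_energy(
    spec: HierarchicalModelSpec, mu: np.ndarray, y_gen: np.ndarray
) -> float:
    """Gaussian free energy (lower is better) at one sample."""
    geo = _Geometry(spec)
    return geo.free_energy(np.asarray(mu, dtype=float), y_gen)


# ---------------------------------------------------------------------------
# the assimilation loop


def _embed_all(values: np.ndarray, order: int) -> np.ndarray:
    """Generalized observations for every sample of a (N, dy) series."""
    N, dy = values.shape
    offsets, E = embedding_matrix(order)
    lo, hi = -offsets[0], N - 1 - offsets[-1]
    out = np.empty((N, order * dy))
    for t in range(N):
        c = min(max(t, lo), hi)
        win = values[c + offsets]  # (order, dy)
        out[t] = (E @ win).ravel()  # order-major
    return out


def initial_posterior(spec: HierarchicalModelSpec, init_state) -> np.ndarray:
    """Flat posterior vector seeded at a state, its flow, and the cause prior."""
    mu = np.zeros(spec.n_mu)
    x0 = np.asarray(init_state, dtype=float)
    if x0.shape != (spec.state_dim,):
        raise ValueError(
            f"initial state must have {spec.state_dim} components"
        )
    v0 = (
        np.asarray(spec.cause_prior_mean, dtype=float)
        if spec.cause_dim
        else np.zeros(0)
    )
    xs = mu[: spec.n_state].reshape(spec.state_order, spec.state_dim)
    xs[0] = x0
    xs[1] = np.asarray(spec.f(x0, v0), dtype=float)
    if spec.cause_dim:
        mu[spec.n_state : spec.n_state + spec.cause_dim] = v0
    return mu


def filter_percept(
    spec: HierarchicalModelSpec,
    percept,
    init_state=None,
    settings: FilterSettings | None = None,
) -> PosteriorTrajectory:
    """Invert a percept under a hierarchical model by generalized filtering.

    ``percept`` may be a PerceptSeries, a 1-D array (scalar outcome) or an
    (N, obs_dim) array.  ``init_state`` seeds the order-0 posterior state
    (defaults to zeros).  Deterministic given inputs and settings.
    """
    if settings is None:
        settings = FilterSettings()
    if isinstance(percept, PerceptSeries):
        values = percept.values[:, None]
        times = percept.times
    else:
        values = np.asarray(percept, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
        times = np.arange(len(values), dtype=float)
    N = len(values)
    if N == 0:
        raise ValueError("percept must be nonempty")
    if values.shape[1] != spec.obs_dim:
        raise ValueError(
            f"percept has {values.shape[1]} channels, model expects {spec.obs_dim}"
        )

    geo = _Geometry(spec)
    y_gen_all = _embed_all(values, spec.state_order)

    mu = initial_posterior(
        spec, np.zeros(spec.state_dim) if init_state is None else init_state
    )

    n_state, dv = spec.n_state, spec.cause_dim
    K = settings.inner_iterations
    out = {
        "state_means": np.empty((N, spec.state_dim)),
        "cause_means": np.empty((N, max(dv, 0))),
        "predicted_obs": np.empty((N, spec.obs_dim)),
        "generalized_means": np.empty((N, spec.n_mu)),
        "raw_outcome_error": np.empty((N, spec.state_order * spec.obs_dim)),
        "raw_dynamics_error": np.empty((N, spec.state_order * spec.state_dim)),
        "raw_cause_error": np.empty((N, spec.cause_order * dv if dv else 0)),
        "free_energy": np.empty(N),
    }
    fe_trace = (
        np.empty((N, K + 1)) if settings.record_free_energy_trace else None
    )

    from scipy.linalg import expm

    D_full = np.zeros((spec.n_mu, spec.n_mu))
    D_full[:n_state, :n_state] = geo.D_state
    if dv:
        D_full[n_state:, n_state:] = geo.D_cause
    tau = 1.0 / K
    n_mu = spec.n_mu

    for t in range(N):
        y_gen = y_gen_all[t]
        errors, jacs = geo.errors(mu, y_gen)
        F = geo.free_energy(mu, y_gen, errors)
        if fe_trace is not None:
            fe_trace[t, 0] = F
        for k in range(K):
            e_v, e_x, e_eta = errors
            J_v, J_x, J_eta = jacs
            grad = J_v.T @ (geo.Pi_v @ e_v) + J_x.T @ (geo.Pi_x @ e_x)
            H = J_v.T @ geo.Pi_v @ J_v + J_x.T @ geo.Pi_x @ J_x
            if e_eta.size:
                grad += J_eta.T @ (geo.Pi_eta @ e_eta)
                H += J_eta.T @ geo.Pi_eta @ J_eta
            # generalized gradient flow: mu' = D mu - rate * dF/dmu,
            # integrated for tau with the local-linearization step
            mu_dot = D_full @ mu - settings.rate * grad
            J = D_full - settings.rate * H
            M = np.zeros((n_mu + 1, n_mu + 1))
            M[:n_mu, :n_mu] = J * tau
            M[:n_mu, n_mu] = mu_dot * tau
            mu = mu + expm(M)[:n_mu, n_mu]
            if not np.all(np.isfinite(mu)):
                raise FilterInstabilityError(t, float("inf"))
            errors, jacs = geo.errors(mu, y_gen)
            F = geo.free_energy(mu, y_gen, errors)
            if fe_trace is not None:
                fe_trace[t, k + 1] = F
        mag = np.max(np.abs(mu))
        if not np.isfinite(mag) or mag > settings.instability_bound:
            raise FilterInstabilityError(t, float(mag))

        xs, vs = spec.split(mu)
        out["state_means"][t] = xs[0]
        if dv:
            out["cause_means"][t] = vs[0]
        out["predicted_obs"][t] = np.atleast_1d(
            spec.g(xs[0], vs[0] if dv else np.zeros(0))
        )
        out["generalized_means"][t] = mu
        e_v, e_x, e_eta = errors
        out["raw_outcome_error"][t] = e_v
        out["raw_dynamics_error"][t] = e_x
        if dv:
            out["raw_cause_error"][t] = e_eta
        out["free_energy"][t] = F

    return PosteriorTrajectory(
        times=times,
        state_means=out["state_means"],
        cause_means=out["cause_means"],
        predicted_obs=out["predicted_obs"],
        generalized_means=out["generalized_means"],
        raw_outcome_error=out["raw_outcome_error"],
        weighted_outcome_error=out["raw_outcome_error"] @ geo.Pi_v.T,
        raw_dynamics_error=out["raw_dynamics_error"],
        weighted_dynamics_error=out["raw_dynamics_error"] @ geo.Pi_x.T,
        raw_cause_error=out["raw_cause_error"],
        weighted_cause_error=(
            out["raw_cause_error"] @ geo.Pi_eta.T
            if dv
            else out["raw_cause_error"]
        ),
        free_energy=out["free_energy"],
        free_energy_trace=fe_trace,
    )
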