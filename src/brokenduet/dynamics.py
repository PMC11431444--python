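"""Classical and broken Lorenz vector fields and their integration.

The Lorenz system

    x' = sigma * (y - x)
    y' = x * (r - z) - y
    z' = x * y - b * z

is used here in a "broken" parameter regime (sigma=0.12, r=0, b=-0.6) in
which the familiar butterfly attractor splits into two disconnected
attracting sets ("lobes") with disjoint basins: trajectories initialised in
one lobe never visit the other.  The sign of x identifies the lobe.  The
field is equivariant under negation of (x, y), which downstream modules
exploit to emulate instantaneous lobe switching in the observation map
rather than in the state.
"""

from __future__ import annotations

from dataclasses import dataclass
import json

import numpy as np
import pandas as pd

__all__ = [
    "LorenzParameters",
    "Trajectory",
    "lorenz_flow",
    "integrate",
    "integrate_batch",
    "lobe_sign",
    "DivergenceError",
    "InvalidStateError",
]

#: Broken-regime parameter values splitting the attractor into two lobes.
BROKEN_SIGMA = 0.12
BROKEN_R = 0.0
BROKEN_B = -0.6

#: Any coordinate exceeding this magnitude during integration is treated as
#: numerical divergence.  Broken-regime trajectories are bounded well below
#: it, so the guard only trips on integrator misuse.
DIVERGENCE_BOUND = 1e6


class InvalidStateError(ValueError):
    """Raised when a state or parameter vector contains non-finite entries."""


class DivergenceError(RuntimeError):
    """Raised when an integrated trajectory leaves the divergence bound."""

    def __init__(self, step: int, state: np.ndarray):
        self.step = step
        self.state = np.asarray(state, dtype=float)
        super().__init__(
            f"trajectory diverged at step {step}: |state| exceeded "
            f"{DIVERGENCE_BOUND:g} (state={self.state})"
        )


@dataclass(frozen=True)
class LorenzParameters:
    """Parameters (sigma, r, b) of the Lorenz equations.

    All three are dimensionless rates.  ``broken()`` returns the regime in
    which the attractor splits into two disconnected lobes; ``classical()``
    returns the textbook chaotic butterfly.
    """

    sigma: float
    r: float
    b: float

    def __post_init__(self):
        vals = (self.sigma, self.r, self.b)
        if not all(np.isfinite(v) for v in vals):
            raise InvalidStateError(f"non-finite Lorenz parameters: {vals}")

    @classmethod
    def broken(cls) -> "LorenzParameters":
        """The bistable regime: sigma=0.12, r=0, b=-0.6."""
        return cls(sigma=BROKEN_SIGMA, r=BROKEN_R, b=BROKEN_B)

    @classmethod
    def classical(cls) -> "LorenzParameters":
        """The textbook chaotic regime: sigma=10, r=28, b=8/3."""
        return cls(sigma=10.0, r=28.0, b=8.0 / 3.0)

    def to_json(self) -> str:
        return json.dumps({"sigma": self.sigma, "r": self.r, "b": self.b})

    @classmethod
    def from_json(cls, text: str) -> "LorenzParameters":
        d = json.loads(text)
        return cls(sigma=d["sigma"], r=d["r"], b=d["b"])


@dataclass(frozen=True)
class Trajectory:
    """A uniformly sampled path of 3-D latent states.

    ``times`` holds sample indices (unit step); ``states`` is an (n, 3)
    array of (x, y, z) rows.
    """

    times: np.ndarray
    states: np.ndarray

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        states = np.asarray(self.states, dtype=float)
        if times.ndim != 1 or len(times) < 1:
            raise ValueError("times must be a non-empty 1-D array")
        if states.shape != (len(times), 3):
            raise ValueError(
                f"states shape {states.shape} incompatible with "
                f"{len(times)} time points"
            )
        dt = np.diff(times)
        if len(dt) and (np.any(dt <= 0) or not np.allclose(dt, dt[0])):
            raise ValueError("times must be strictly increasing and uniform")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "states", states)

    def __len__(self) -> int:
        return len(self.times)

    @property
    def x(self) -> np.ndarray:
        return self.states[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.states[:, 1]

    @property
    def z(self) -> np.ndarray:
        return self.states[:, 2]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.times, "x": self.x, "y": self.y, "z": self.z}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path)
        return cls(df["t"].to_numpy(), df[["x", "y", "z"]].to_numpy())


def _as_state(state) -> np.ndarray:
    s = np.asarray(state, dtype=float)
    if s.shape != (3,):
        raise InvalidStateError(f"state must have 3 components, got {s.shape}")
    if not np.all(np.isfinite(s)):
        raise InvalidStateError(f"non-finite state: {s}")
    return s


def lorenz_flow(state, params: LorenzParameters) -> np.ndarray:
    """Time derivative of the Lorenz equations at ``state``.

    Returns (sigma*(y-x), x*(r-z)-y, x*y-b*z).
    """
    x, y, z = _as_state(state)
    return np.array(
        [
            params.sigma * (y - x),
            x * (params.r - z) - y,
            x * y - params.b * z,
        ]
    )


def lorenz_jacobian(state, params: LorenzParameters) -> np.ndarray:
    """Jacobian of the Lorenz flow with respect to (x, y, z)."""
    x, y, z = _as_state(state)
    return np.array(
        [
            [-params.sigma, params.sigma, 0.0],
            [params.r - z, -1.0, -x],
            [y, x, -params.b],
        ]
    )


def _rk4_step(state: np.ndarray, params: LorenzParameters, h: float) -> np.ndarray:
    k1 = lorenz_flow(state, params)
    k2 = lorenz_flow(state + 0.5 * h * k1, params)
    k3 = lorenz_flow(state + 0.5 * h * k2, params)
    k4 = lorenz_flow(state + h * k3, params)
    return state + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)


def _ll_step(state: np.ndarray, params: LorenzParameters, h: float) -> np.ndarray:
    # Local linearization (Ozaki): exact flow of the tangent-linear system.
    from scipy.linalg import expm

    f = lorenz_flow(state, params)
    J = lorenz_jacobian(state, params)
    Jh = J * h
    # phi = (expm(Jh) - I) J^{-1}; computed via an augmented exponential so
    # singular Jacobians are handled without explicit inversion.
    n = 3
    M = np.zeros((n + 1, n + 1))
    M[:n, :n] = Jh
    M[:n, n] = h * f
    E = expm(M)
    return state + E[:n, n]


_STEPPERS = {"rk4": _rk4_step, "local_linear": _ll_step}


def integrate(
    initial,
    params: LorenzParameters,
    n_steps: int,
    dt: float = 1.0,
    method: str = "rk4",
    substeps: int = 4,
) -> Trajectory:
    """Integrate the Lorenz system for ``n_steps`` samples of size ``dt``.

    One sample is one unit of model time by default; each sample is taken
    with ``substeps`` internal integrator steps to keep local error small.
    The returned trajectory has ``n_steps + 1`` points starting at
    ``initial`` and is deterministic given all arguments.

    Raises
    ------
    DivergenceError
        if any coordinate magnitude exceeds the divergence bound.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if dt <= 0:
        raise ValueError("dt must be positive")
    if substeps < 1:
        raise ValueError("substeps must be >= 1")
    try:
        stepper = _STEPPERS[method]
    except KeyError:
        raise ValueError(
            f"unknown method {method!r}; choose from {sorted(_STEPPERS)}"
        ) from None

    h = dt / substeps
    states = np.empty((n_steps + 1, 3))
    s = _as_state(initial)
    states[0] = s
    for i in range(1, n_steps + 1):
        for _ in range(substeps):
            s = stepper(s, params, h)
        if np.any(np.abs(s) > DIVERGENCE_BOUND) or not np.all(np.isfinite(s)):
            raise DivergenceError(i, s)
        states[i] = s
    return Trajectory(np.arange(n_steps + 1, dtype=float) * dt, states)


def integrate_batch(
    initials,
    params: LorenzParameters,
    n_steps: int,
    dt: float = 1.0,
    substeps: int = 4,
    on_divergence: str = "raise",
) -> np.ndarray:
    """Integrate many initial states at once with classical RK4.

    ``initials`` is an (m, 3) array.  Returns an (m, n_steps + 1, 3) array
    of states.  Vectorised across trajectories, which keeps ensemble
    confinement checks (many trajectories, many steps) fast.

    ``on_divergence`` controls escaping trajectories: "raise" aborts with
    a DivergenceError; "mask" freezes an escaped trajectory at NaN from
    the escaping step onward and continues the rest.  The broken regime's
    attracting sets have thin basins, so ensembles perturbed off the
    attractor can contain genuinely escaping members.
    """
    if on_divergence not in ("raise", "mask"):
        raise ValueError("on_divergence must be 'raise' or 'mask'")
    if n_steps < 1 or dt <= 0 or substeps < 1:
        raise ValueError("n_steps >= 1, dt > 0 and substeps >= 1 required")
    S = np.asarray(initials, dtype=float)
    if S.ndim != 2 or S.shape[1] != 3:
        raise InvalidStateError("initials must be an (m, 3) array")
    if not np.all(np.isfinite(S)):
        raise InvalidStateError("non-finite initial states")

    def flow(S):
        x, y, z = S[:, 0], S[:, 1], S[:, 2]
        return np.stack(
            [
                params.sigma * (y - x),
                x * (params.r - z) - y,
                x * y - params.b * z,
            ],
            axis=1,
        )

    h = dt / substeps
    out = np.empty((S.shape[0], n_steps + 1, 3))
    out[:, 0] = S
    with np.errstate(over="ignore", invalid="ignore"):
        for i in range(1, n_steps + 1):
            for _ in range(substeps):
                k1 = flow(S)
                k2 = flow(S + 0.5 * h * k1)
                k3 = flow(S + 0.5 * h * k2)
                k4 = flow(S + h * k3)
                S = S + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            escaped = np.any(np.abs(S) > DIVERGENCE_BOUND, axis=1) | ~np.all(
                np.isfinite(S), axis=1
            )
            if np.any(escaped):
                if on_divergence == "raise":
                    bad = np.flatnonzero(escaped)[0]
                    raise DivergenceError(i, S[bad])
                S[escaped] = np.nan
            out[:, i] = S
    return out


def lobe_sign(state) -> int:
    """Which lobe of the broken attractor a state belongs to: sign of x.

    The two attracting sets are separated along the x coordinate.  The
    measure-zero boundary x == 0 is assigned +1 by convention.
    """
    x = _as_state(state)[0]
    return 1 if x >= 0 else -1
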