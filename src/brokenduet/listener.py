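"""The listener's two-level generative model of the ambiguous percept.

Level 1: broken-Lorenz dynamics on (x~, y~, z~) with the observation

    v0~ = 0.5 * tanh(v1~) * y~ + z~

where tanh maps the listener's real-valued lobe belief v1~ into (-1, 1) so
that it can smoothly interpolate between the two lobes' observation maps.
Level 2: the lobe cause is static (zero predicted dynamics) with a
Gaussian prior of mean 1 and log-precision -1 -- a listener initially
confident the +1 lobe generated the data, but open to revision.

The four named precision regimes cross internal (dynamics) and external
(outcome) log-precisions over {0, 4}:

    A = (0, 0)   B = (4, 0)   C = (0, 4)   D = (4, 4)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import LorenzParameters, lorenz_flow, lorenz_jacobian
from .filtering import HierarchicalModelSpec, PosteriorTrajectory
from .gencoords import SmoothnessModel

__all__ = [
    "PrecisionConfig",
    "build_listener_model",
    "lobe_estimate",
    "LISTENER_INIT",
    "LOBE_PRIOR_MEAN",
    "LOBE_PRIOR_LOG_PRECISION",
]

#: Study-protocol listener initial state (mirror lobe of the speaker's).
LISTENER_INIT = (-0.8, 3.0, 0.0)
LOBE_PRIOR_MEAN = 1.0
LOBE_PRIOR_LOG_PRECISION = -1.0

_REGIMES = {"A": (0.0, 0.0), "B": (4.0, 0.0), "C": (0.0, 4.0), "D": (4.0, 4.0)}


@dataclass(frozen=True)
class PrecisionConfig:
    """Internal (dynamics) and external (outcome) log-precisions."""

    internal_log_precision: float
    external_log_precision: float
    label: str = "custom"

    @classmethod
    def from_label(cls, label: str) -> "PrecisionConfig":
        try:
            li, le = _REGIMES[label.upper()]
        except KeyError:
            raise ValueError(
                f"unknown regime {label!r}; expected one of {sorted(_REGIMES)}"
            ) from None
        return cls(li, le, label.upper())

    @classmethod
    def A(cls) -> "PrecisionConfig":
        return cls.from_label("A")

    @classmethod
    def B(cls) -> "PrecisionConfig":
        return cls.from_label("B")

    @classmethod
    def C(cls) -> "PrecisionConfig":
        return cls.from_label("C")

    @classmethod
    def D(cls) -> "PrecisionConfig":
        return cls.from_label("D")


def build_listener_model(
    config: PrecisionConfig,
    params: LorenzParameters | None = None,
    lobe_prior_mean: float = LOBE_PRIOR_MEAN,
    lobe_prior_log_precision: float = LOBE_PRIOR_LOG_PRECISION,
    state_order: int = 6,
    cause_order: int = 2,
    smoothness: SmoothnessModel | None = None,
    time_step: float = 1.0,
) -> HierarchicalModelSpec:
    """Assemble the listener's hierarchical model under a precision regime.

    The listener shares the speaker's broken-Lorenz parameters.
    ``time_step`` is the model time covered by one percept sample; the
    evolution map is expressed per sample, so it must match the speaker's
    generation time step.  Building is pure: identical arguments give
    identical specs.
    """
    if params is None:
        params = LorenzParameters.broken()
    if smoothness is None:
        smoothness = SmoothnessModel()

    def f(x, v):
        return time_step * lorenz_flow(x, params)

    def g(x, v):
        return np.array([0.5 * np.tanh(v[0]) * x[1] + x[2]])

    def fx(x, v):
        return time_step * lorenz_jacobian(x, params)

    def fv(x, v):
        return np.zeros((3, 1))

    def gx(x, v):
        return np.array([[0.0, 0.5 * np.tanh(v[0]), 1.0]])

    def gv(x, v):
        sech2 = 1.0 / np.cosh(v[0]) ** 2
        return np.array([[0.5 * sech2 * x[1]]])

    return HierarchicalModelSpec(
        f=f,
        g=g,
        state_dim=3,
        obs_dim=1,
        cause_dim=1,
        internal_log_precision=config.internal_log_precision,
        external_log_precision=config.external_log_precision,
        cause_prior_mean=(lobe_prior_mean,),
        cause_prior_log_precision=lobe_prior_log_precision,
        state_order=state_order,
        cause_order=cause_order,
        smoothness=smoothness,
        fx=fx,
        fv=fv,
        gx=gx,
        gv=gv,
    )


def lobe_estimate(
    posterior: PosteriorTrajectory, window: int | None = None
) -> float:
    """Signed lobe belief in [-1, 1]: mean of tanh(v1~) over a trailing window.

    Defaults to the final quarter of the trajectory, reflecting the
    converged belief rather than the transient.
    """
    n = len(posterior)
    if window is None:
        window = max(1, n // 4)
    if window > n:
        raise ValueError(f"window {window} exceeds trajectory length {n}")
    v1 = posterior.cause_means[-window:, 0]
    return float(np.mean(np.tanh(v1)))
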