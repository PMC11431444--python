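"""The speaker's generative process: latent dynamics, lobe schedule, percept.

The speaker's internal state follows the broken Lorenz system; the only
signal crossing to the listener is the scalar percept

    v0 = 0.5 * v1 * y + z

where v1 in {-1, +1} is a second-level "lobe" cause.  The percept omits x
-- the coordinate along which the two lobes are separated -- so it is
deliberately ambiguous: the map is invariant under (y, v1) -> (-y, -v1).
Lobe switching is emulated purely in the observation map, exploiting the
(x, y)-negation symmetry of the Lorenz field, so the latent trajectory is
integrated continuously across switches.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .dynamics import LorenzParameters, Trajectory, integrate

__all__ = [
    "LobeSchedule",
    "PerceptSeries",
    "make_lobe_schedule",
    "observe",
    "generate_percept",
]


@dataclass(frozen=True)
class LobeSchedule:
    """Piecewise-constant lobe cause v1(t) in {-1, +1}, one value per sample."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or len(v) < 1:
            raise ValueError("schedule must be a non-empty 1-D sequence")
        if not np.all(np.isin(v, (-1.0, 1.0))):
            raise ValueError("schedule values must be -1 or +1")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n_samples(self) -> int:
        return len(self.values)

    @property
    def switch_indices(self) -> np.ndarray:
        """Indices i where values[i] differs from values[i-1]."""
        return np.flatnonzero(np.diff(self.values)) + 1

    @classmethod
    def constant(cls, n_samples: int, value: int = 1) -> "LobeSchedule":
        return cls(np.full(n_samples, float(value)))


@dataclass(frozen=True)
class PerceptSeries:
    """Scalar percept time series v0(t), with the noise level that produced it."""

    times: np.ndarray
    values: np.ndarray
    noise_sd: float = 0.0

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if t.shape != v.shape or t.ndim != 1:
            raise ValueError("times and values must be 1-D of equal length")
        if not np.all(np.isfinite(v)):
            raise ValueError("percept contains non-finite values")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self, schedule: LobeSchedule | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"t": self.times, "v0": self.values})
        if schedule is not None:
            df["v1"] = schedule.values
        return df

    def to_csv(self, path, schedule: LobeSchedule | None = None) -> None:
        self.to_frame(schedule).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "PerceptSeries":
        df = pd.read_csv(path)
        return cls(df["t"].to_numpy(), df["v0"].to_numpy())


def make_lobe_schedule(
    n_samples: int, period: int, start: int = 1
) -> LobeSchedule:
    """Square-wave schedule alternating lobe every ``period`` samples.

    A period longer than the series yields a single-lobe schedule (with a
    warning), which is the protocol used for the non-switching simulations.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if period < 1:
        raise ValueError("period must be >= 1")
    if start not in (-1, 1):
        raise ValueError("start must be -1 or +1")
    if period > n_samples:
        warnings.warn(
            f"period {period} exceeds series length {n_samples}; "
            "returning a single-lobe schedule",
            stacklevel=2,
        )
        return LobeSchedule.constant(n_samples, start)
    blocks = (np.arange(n_samples) // period) % 2
    values = np.where(blocks == 0, float(start), -float(start))
    return LobeSchedule(values)


def observe(state, v1: float) -> float:
    """The ambiguous percept map: v0 = 0.5 * v1 * y + z.

    Independent of x, so the lobe is never directly observable.
    """
    s = np.asarray(state, dtype=float)
    if s.shape[-1] != 3:
        raise ValueError("state must have 3 components")
    return 0.5 * v1 * s[..., 1] + s[..., 2]


def generate_percept(
    params: LorenzParameters | None = None,
    initial=(0.8, -3.0, 0.0),
    schedule: LobeSchedule | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
    n_samples: int = 16384,
    time_step: float = 1.0,
    substeps: int = 4,
    method: str = "rk4",
) -> tuple[Trajectory, PerceptSeries]:
    """Run the speaker's generative process.

    Integrates the (by default broken) Lorenz system from ``initial`` at
    ``time_step`` model-time units per sample, applies the observation map
    with the schedule's per-sample lobe cause, and adds independent
    Gaussian noise of standard deviation ``noise_sd``.  Fully reproducible
    given ``seed``.  At the default time step one quasi-period of the
    percept spans roughly ten samples.

    Returns the latent trajectory and the percept series (both of length
    ``len(schedule)``, or ``n_samples`` if no schedule is given).
    """
    if params is None:
        params = LorenzParameters.broken()
    if schedule is None:
        schedule = LobeSchedule.constant(n_samples, 1)
    n = len(schedule)
    traj = integrate(
        initial, params, n_steps=n - 1, dt=time_step, method=method,
        substeps=substeps,
    )
    clean = 0.5 * schedule.values * traj.y + traj.z
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        values = clean + rng.normal(0.0, noise_sd, size=n)
    else:
        values = clean
    percept = PerceptSeries(traj.times, values, noise_sd=noise_sd)
    return traj, percept
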