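"""Generalized coordinates of motion.

A signal is represented at each instant by the stack of its temporal
derivatives up to a fixed embedding order n: u = (u, u', u'', ...).  Three
pieces of machinery are needed:

* the block shift (derivative) operator D mapping each order to the next;
* local embedding of a sampled series into derivative estimates, by
  inverting the Taylor map of a symmetric window of samples (exact for
  polynomials of degree < n);
* the precision over derivative orders implied by analytic Gaussian noise
  with a Gaussian autocorrelation of a given width ("smoothness"), which
  couples even orders and leaves odd-even cross terms zero.

Conventions: generalized vectors of a d-dimensional signal are stored
order-major, i.e. (order 0 components..., order 1 components, ...), so a
generalized precision for the full vector is kron(S, I_d) with S the
scalar-signal precision returned here.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import factorial

import numpy as np

__all__ = [
    "SmoothnessModel",
    "shift_operator",
    "embed_series",
    "embedding_matrix",
    "generalized_precision",
    "generalized_covariance",
    "BoundaryError",
    "ConditioningError",
]


class BoundaryError(IndexError):
    """Embedding window does not fit inside the series."""


class ConditioningError(np.linalg.LinAlgError):
    """A precision matrix failed to be numerically positive definite."""


@dataclass(frozen=True)
class SmoothnessModel:
    """Autocorrelation width and base log-precision of analytic noise.

    ``smoothness`` is the width s (in sample-time units) of the Gaussian
    autocorrelation rho(h) = exp(-h^2 / (4 s^2)); under this convention the
    first derivative of a unit-variance noise process has variance
    1 / (2 s^2).  ``base_log_precision`` scales the whole precision by
    exp(base_log_precision).
    """

    smoothness: float = 0.5
    base_log_precision: float = 0.0

    def __post_init__(self):
        if not (self.smoothness > 0):
            raise ValueError("smoothness must be positive")


def shift_operator(order: int, dim: int = 1) -> np.ndarray:
    """Block derivative operator on order-major generalized vectors.

    Maps (u0, u1, ..., u_{n-1}) to (u1, ..., u_{n-1}, 0); nilpotent of
    index ``order``.  For a dim-d signal returns kron(D, I_d).
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    D = np.eye(order, k=1)
    if dim == 1:
        return D
    return np.kron(D, np.eye(dim))


def embedding_matrix(order: int) -> tuple[np.ndarray, np.ndarray]:
    """Inverse Taylor map of a symmetric sample window.

    Returns (offsets, E) with offsets the ``order`` integer sample offsets
    centred on 0 and E the (order, order) matrix such that E @ s_window
    gives derivative estimates (u0 ... u_{n-1}) at the window centre.
    Exact for polynomials of degree < order.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    offsets = np.arange(order) - (order - 1) // 2
    T = np.array(
        [[k**j / factorial(j) for j in range(order)] for k in offsets],
        dtype=float,
    )
    return offsets, np.linalg.inv(T)


def embed_series(series, order: int, center: int) -> np.ndarray:
    """Local derivative estimates of a scalar series around ``center``.

    The first and last half-windows reuse the nearest interior window (the
    derivative estimates are those of the closest centre for which the
    full symmetric window exists), so no derivatives are fabricated by
    extrapolation.
    """
    s = np.asarray(series, dtype=float)
    if s.ndim != 1:
        raise ValueError("series must be 1-D")
    n = len(s)
    if order > n:
        raise BoundaryError(
            f"embedding order {order} exceeds series length {n}"
        )
    if not (0 <= center < n):
        raise BoundaryError(f"center {center} outside series of length {n}")
    offsets, E = embedding_matrix(order)
    lo, hi = -offsets[0], n - 1 - offsets[-1]
    c = min(max(center, lo), hi)
    return E @ s[c + offsets]


def generalized_covariance(smooth: SmoothnessModel, order: int) -> np.ndarray:
    """Covariance over derivative orders of analytic Gaussian noise.

    Entry (i, j) is the signed (i+j)-th derivative at zero lag of the
    Gaussian autocovariance, zero for odd i+j; scaled by
    exp(-base_log_precision).
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    a = 1.0 / (4.0 * smooth.smoothness**2)
    C = np.zeros((order, order))
    for i in range(order):
        for j in range(order):
            k = i + j
            if k % 2:
                continue
            m = k // 2
            # rho^{(2m)}(0) = (-a)^m (2m)!/m! for rho(h)=exp(-a h^2)
            C[i, j] = (-1.0) ** j * (-a) ** m * factorial(k) / factorial(m)
    return C * np.exp(-smooth.base_log_precision)


def generalized_precision(smooth: SmoothnessModel, order: int) -> np.ndarray:
    """Precision (inverse covariance) over derivative orders.

    Symmetric positive definite; raises ConditioningError if numerical
    inversion loses positive definiteness.
    """
    C = generalized_covariance(smooth, order)
    P = np.linalg.inv(C)
    P = 0.5 * (P + P.T)
    eigmin = np.linalg.eigvalsh(P)[0]
    if not np.isfinite(eigmin) or eigmin <= 0:
        raise ConditioningError(
            f"generalized precision not positive definite "
            f"(order={order}, smoothness={smooth.smoothness}, "
            f"min eigenvalue={eigmin:g})"
        )
    return P
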