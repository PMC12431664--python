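"""Exact moments of the filament length-change distribution.

For a filament switching between N states with generator ``K`` and per-state
length-step rates (r_i up, gamma_j down), the joint law of (state, length
change) obeys a chemical master equation.  Multiplying it by ``dL^x`` and
summing over the length coordinate closes the dynamics of the partial-moment
vectors ``M^(x)_i(t) = sum_dL dL^x P_i(dL, t)`` into a block-lower-triangular
linear ODE:

    dM^(x)/dt = K M^(x) + sum_{y<x} C(x, y) [R_up + (-1)^(x-y) R_dn] M^(y),

with ``M^(0)(0)`` the initial state occupancy and ``M^(x>=1)(0) = 0``.  The
n-th moment of the length change is ``<dL_t^n> = sum_i M^(n)_i(t)``.  The
hierarchy is solved exactly by the matrix exponential of the augmented
(n+1)N x (n+1)N system, so transient moments carry no discretization error.

Long-time window statistics — moments of the length change accumulated over a
window tau opened after the state occupancies have relaxed to stationarity —
are the same propagation started from the stationary distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import comb
from typing import Literal

import numpy as np
import pandas as pd
from scipy.linalg import expm, null_space

from .model import KineticModel

TRANSIENT = "transient"
LONGTIME = "longtime_window"

_MAX_SAFE_ORDER = 4

__all__ = [
    "ReducibleModelError",
    "MomentCurve",
    "MomentSummary",
    "stationary_distribution",
    "transient_moment",
    "longtime_moment",
    "moment_summary",
]


class ReducibleModelError(RuntimeError):
    """The switching graph is not irreducible: no unique stationary law."""


@dataclass(frozen=True)
class MomentCurve:
    """Moment <dL^n> of the length-change distribution on a time grid.

    ``regime`` is "transient" (grid = elapsed time t, fixed initial
    occupancy) or "longtime_window" (grid = window length tau, stationary
    start).  Values are in subunits^n.
    """

    regime: str
    order: int
    grid: np.ndarray
    values: np.ndarray
    initial_distribution: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "regime": self.regime,
                "n": self.order,
                "t_or_tau": self.grid,
                "value": self.values,
                "units": f"subunits^{self.order}",
            }
        )


@dataclass(frozen=True)
class MomentSummary:
    """Mean, variance and Fano factor of dL on a common grid.

    ``fano = variance / mean`` (units: subunits); where the mean vanishes the
    Fano factor is undefined and reported as NaN.
    """

    regime: str
    grid: np.ndarray
    mean: np.ndarray
    variance: np.ndarray
    fano: np.ndarray
    initial_distribution: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "regime": self.regime,
                "t_or_tau": self.grid,
                "mean": self.mean,
                "variance": self.variance,
                "fano": self.fano,
            }
        )


def _check_distribution(model: KineticModel, p0: np.ndarray) -> np.ndarray:
    p0 = np.asarray(p0, dtype=float)
    if p0.shape != (model.n_states,):
        raise ValueError(
            f"initial distribution has shape {p0.shape}, expected ({model.n_states},)"
        )
    if np.any(p0 < -1e-12):
        raise ValueError("initial distribution has negative entries")
    if abs(p0.sum() - 1.0) > 1e-9:
        raise ValueError(f"initial distribution sums to {p0.sum()}, not 1")
    return p0


def stationary_distribution(model: KineticModel, tol: float = 1e-10) -> np.ndarray:
    """Stationary occupancy pi with K pi = 0, sum(pi) = 1.

    Raises :class:`ReducibleModelError` when the switching graph has more
    than one closed communicating class (no unique stationary law exists); a
    silent pseudo-inverse is never used.  Transient states — e.g. the bound
    state at zero regulator concentration — are allowed and receive zero
    stationary mass.
    """
    if model.n_closed_classes() != 1:
        raise ReducibleModelError(
            "switching graph has multiple closed classes: "
            "no unique stationary distribution"
        )
    K = model.generator
    ns = null_space(K)
    if ns.shape[1] != 1:
        raise ReducibleModelError(
            f"generator null space has dimension {ns.shape[1]}, expected 1"
        )
    pi = ns[:, 0]
    pi = pi / pi.sum()
    pi = np.clip(pi, 0.0, None)
    pi = pi / pi.sum()
    scale = max(1.0, float(np.abs(K).max()))
    residual = float(np.abs(K @ pi).max())
    if residual > tol * scale:
        raise ReducibleModelError(
            f"stationary solve residual {residual:.3e} exceeds tolerance"
        )
    return pi


def _augmented_generator(model: KineticModel, order: int) -> np.ndarray:
    n_states = model.n_states
    K = model.generator
    r_up = np.diag(model.rate_up)
    r_dn = np.diag(model.rate_down)
    size = (order + 1) * n_states
    A = np.zeros((size, size))
    for x in range(order + 1):
        sl_x = slice(x * n_states, (x + 1) * n_states)
        A[sl_x, sl_x] = K
        for y in range(x):
            sign = (-1) ** (x - y)
            A[sl_x, y * n_states : (y + 1) * n_states] = comb(x, y) * (
                r_up + sign * r_dn
            )
    return A


def partial_moments(
    model: KineticModel,
    initial_distribution: np.ndarray,
    order: int,
    times: np.ndarray,
) -> np.ndarray:
    """Partial-moment vectors M^(0..order) at each time.

    Returns an array of shape ``(len(times), order + 1, N)``; summing the last
    axis of slice ``[:, x, :]`` gives <dL^x>.  Exposed for diagnostics such as
    occupancy-conservation checks (``M^(0)`` sums to 1 at every time).
    """
    p0 = _check_distribution(model, initial_distribution)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    if order < 0:
        raise ValueError("order must be >= 0")
    if order > _MAX_SAFE_ORDER:
        warnings.warn(
            f"moment order {order} > {_MAX_SAFE_ORDER}: high-order moments are "
            "numerically delicate",
            stacklevel=2,
        )
    n_states = model.n_states
    A = _augmented_generator(model, order)
    m0 = np.zeros((order + 1) * n_states)
    m0[:n_states] = p0
    out = np.empty((times.size, order + 1, n_states))
    for k, t in enumerate(times):
        if t == 0.0:
            out[k] = m0.reshape(order + 1, n_states)
        else:
            out[k] = (expm(A * t) @ m0).reshape(order + 1, n_states)
    return out


def transient_moment(
    model: KineticModel,
    initial_distribution: np.ndarray,
    n: int,
    times: np.ndarray,
) -> MomentCurve:
    """Transient n-th moment <dL_t^n> from a given initial state occupancy."""
    if n < 1:
        raise ValueError("moment order n must be >= 1")
    times = np.atleast_1d(np.asarray(times, dtype=float))
    blocks = partial_moments(model, initial_distribution, n, times)
    values = blocks[:, n, :].sum(axis=1)
    return MomentCurve(
        regime=TRANSIENT,
        order=n,
        grid=times,
        values=values,
        initial_distribution=np.asarray(initial_distribution, dtype=float),
    )


def longtime_moment(model: KineticModel, n: int, tau: np.ndarray) -> MomentCurve:
    """Long-time windowed n-th moment <dL_tau^n>.

    The window opens after the switching process has reached stationarity, so
    this is the transient moment started from the stationary occupancy and
    evaluated at t = tau.
    """
    tau = np.atleast_1d(np.asarray(tau, dtype=float))
    if np.any(tau < 0):
        raise ValueError("window lengths tau must be >= 0")
    pi = stationary_distribution(model)
    curve = transient_moment(model, pi, n, tau)
    return MomentCurve(
        regime=LONGTIME,
        order=n,
        grid=tau,
        values=curve.values,
        initial_distribution=pi,
    )


def _fano(mean: np.ndarray, variance: np.ndarray) -> np.ndarray:
    # undefined (NaN sentinel) where the mean vanishes to working precision
    atol = 1e-10 * np.maximum(1.0, np.abs(variance))
    defined = np.abs(mean) > atol
    fano = np.full_like(mean, np.nan)
    np.divide(variance, mean, out=fano, where=defined)
    return fano


def moment_summary(
    model: KineticModel,
    regime: Literal["transient", "longtime_window"],
    grid: np.ndarray,
    initial_distribution: np.ndarray | None = None,
) -> MomentSummary:
    """Mean, variance and Fano factor of dL over a grid of t (or tau).

    In the transient regime the filament starts from ``initial_distribution``
    (default: all mass in the first state, the bare state for the canonical
    builders).  In the long-time-window regime the start is the stationary
    occupancy and ``initial_distribution`` must not be supplied.
    """
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    if regime == TRANSIENT:
        if initial_distribution is None:
            p0 = np.zeros(model.n_states)
            p0[0] = 1.0
        else:
            p0 = _check_distribution(model, initial_distribution)
    elif regime == LONGTIME:
        if initial_distribution is not None:
            raise ValueError(
                "longtime_window regime always starts from the stationary "
                "distribution; do not pass initial_distribution"
            )
        p0 = stationary_distribution(model)
    else:
        raise ValueError(f"unknown regime {regime!r}")
    blocks = partial_moments(model, p0, 2, grid)
    mean = blocks[:, 1, :].sum(axis=1)
    second = blocks[:, 2, :].sum(axis=1)
    variance = second - mean**2
    return MomentSummary(
        regime=regime,
        grid=grid,
        mean=mean,
        variance=variance,
        fano=_fano(mean, variance),
        initial_distribution=p0,
    )
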