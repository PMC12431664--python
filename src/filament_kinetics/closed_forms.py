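"""Analytic mean and variance of filament length change for the two-state
regulator models.

Eight closed-form expressions: transient and long-time-window mean/variance
for the elongator scheme (bare state B at rate r1 <-> bound state BF at rate
r2) and for the capper scheme (B at rate r1 <-> capped state BC at rate 0).
Transient expressions assume the filament starts in the bare state B; the
long-time-window expressions assume stationary state occupancy when the
observation window opens.

All expressions are parameterized by the total switching rate D = k+ + k- and
the stationary bare-state occupancy A = k-/D.  They serve as the analytic
oracle for the general moment engine and as fast evaluators for concentration
sweeps; the engine, in turn, guards against transcription slips here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import RegulatorKinetics

__all__ = [
    "TwoStateParams",
    "elongator_transient_mean",
    "elongator_transient_variance",
    "elongator_longtime_mean",
    "elongator_longtime_variance",
    "capper_transient_mean",
    "capper_transient_variance",
    "capper_longtime_mean",
    "capper_longtime_variance",
]


@dataclass(frozen=True)
class TwoStateParams:
    """Rates of a two-state switching model.

    r1, r2 in subunits/s; k_plus = k~+ [X] and k_minus in s^-1.  Derived:
    D = k_plus + k_minus and A = k_minus / D, the stationary occupancy of the
    bare state.  When both switching rates vanish (D = 0) the filament never
    leaves the bare state; A is then taken as 1 so every expression reduces to
    the pure one-state (Poisson) limit rather than dividing by zero.
    """

    r1: float
    r2: float
    k_plus: float
    k_minus: float

    def __post_init__(self) -> None:
        for attr in ("r1", "r2", "k_plus", "k_minus"):
            v = getattr(self, attr)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{attr} must be finite and >= 0, got {v}")

    @property
    def D(self) -> float:
        # a total switching rate whose square underflows is numerically
        # indistinguishable from a non-switching filament
        d = self.k_plus + self.k_minus
        return d if d * d > 0.0 else 0.0

    @property
    def A(self) -> float:
        return 1.0 if self.D == 0.0 else self.k_minus / self.D

    @classmethod
    def for_elongator(
        cls, r1: float, r2: float, elongator: RegulatorKinetics
    ) -> "TwoStateParams":
        return cls(r1, r2, elongator.on_rate, elongator.off_rate)

    @classmethod
    def for_capper(cls, r1: float, capper: RegulatorKinetics) -> "TwoStateParams":
        return cls(r1, 0.0, capper.on_rate, capper.off_rate)


def _one_minus_exp(d: float, t: np.ndarray) -> np.ndarray:
    """(1 - exp(-d t)), stable for both tiny and huge d*t."""
    return -np.expm1(-d * t)


# ---------------------------------------------------------------------------
# elongator (B at r1 <-> BF at r2)
# ---------------------------------------------------------------------------


def elongator_transient_mean(p: TwoStateParams, t) -> np.ndarray:
    """<dL_t> for the elongator model, start in B."""
    t = np.asarray(t, dtype=float)
    if p.D == 0.0:
        return p.r1 * t
    c = p.r1 - p.r2
    return p.r2 * t + c * p.A * t + c * (1.0 - p.A) / p.D * _one_minus_exp(p.D, t)


def elongator_transient_variance(p: TwoStateParams, t) -> np.ndarray:
    """Var(dL_t) for the elongator model, start in B."""
    t = np.asarray(t, dtype=float)
    if p.D == 0.0:
        return p.r1 * t
    A, D = p.A, p.D
    c = p.r1 - p.r2
    b = 1.0 - A
    e = np.exp(-D * t)
    linear = p.r2 * t + c * A * t + 2.0 * A * b * c**2 / D * t
    const = c * b * (D + c * (1.0 - 5.0 * A)) / D**2
    decay2 = -((b * c / D) ** 2) * e**2
    decay1 = b * c / D**2 * (4.0 * A * c - D * (1.0 + 2.0 * (1.0 - 2.0 * A) * c * t)) * e
    return linear + const + decay2 + decay1


def elongator_longtime_mean(p: TwoStateParams, tau) -> np.ndarray:
    """<dL_tau> over a window tau opened at stationarity; exactly linear in tau."""
    tau = np.asarray(tau, dtype=float)
    if p.D == 0.0:
        return p.r1 * tau
    return p.r2 * tau + (p.r1 - p.r2) * p.A * tau


def elongator_longtime_variance(p: TwoStateParams, tau) -> np.ndarray:
    """Var(dL_tau) over a window tau opened at stationarity."""
    tau = np.asarray(tau, dtype=float)
    if p.D == 0.0:
        return p.r1 * tau
    A, D = p.A, p.D
    c = p.r1 - p.r2
    ab = A * (1.0 - A)
    return (
        p.r2 * tau
        + c * A * tau
        + 2.0 / D * c**2 * ab * tau
        - 2.0 / D**2 * c**2 * ab * _one_minus_exp(D, tau)
    )


# ---------------------------------------------------------------------------
# capper (B at r1 <-> BC at 0)
# ---------------------------------------------------------------------------


def capper_transient_mean(p: TwoStateParams, t) -> np.ndarray:
    """<dL_t> for the capper model, start in B."""
    t = np.asarray(t, dtype=float)
    if p.D == 0.0:
        return p.r1 * t
    return p.r1 * p.A * t + p.r1 * (1.0 - p.A) / p.D * _one_minus_exp(p.D, t)


def capper_transient_variance(p: TwoStateParams, t) -> np.ndarray:
    """Var(dL_t) for the capper model, start in B."""
    t = np.asarray(t, dtype=float)
    if p.D == 0.0:
        return p.r1 * t
    A, D, r1 = p.A, p.D, p.r1
    b = 1.0 - A
    e = np.exp(-D * t)
    return (
        r1 * A * t
        + r1 * b / D * _one_minus_exp(D, t)
        + 2.0 * r1**2 * A * b * t / D
        + (r1 * b / D) ** 2 * _one_minus_exp(2.0 * D, t)
        - 2.0 * r1**2 * b / D**2 * _one_minus_exp(D, t)
        + 2.0 * r1**2 * b * (1.0 - 2.0 * A) / D**2 * (1.0 - (1.0 + D * t) * e)
    )


def capper_longtime_mean(p: TwoStateParams, tau) -> np.ndarray:
    """<dL_tau> for the capper model: r1 * A * tau."""
    tau = np.asarray(tau, dtype=float)
    if p.D == 0.0:
        return p.r1 * tau
    return p.r1 * p.A * tau


def capper_longtime_variance(p: TwoStateParams, tau) -> np.ndarray:
    """Var(dL_tau) for the capper model over a stationary window."""
    tau = np.asarray(tau, dtype=float)
    if p.D == 0.0:
        return p.r1 * tau
    A, D, r1 = p.A, p.D, p.r1
    ab = A * (1.0 - A)
    return (
        r1 * A * tau
        + 2.0 / D * r1**2 * ab * tau
        - 2.0 / D**2 * r1**2 * ab * _one_minus_exp(D, tau)
    )
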