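"""Empirical statistics over filament trajectory ensembles.

Cross-filament mean/variance of the length change, time-resolved Fano factor
with percentile-bootstrap confidence bands (resampling whole filaments, which
preserves within-trajectory correlation), and the sample-size formula for
planning how many filaments a target relative error in the Fano factor
requires.

All statistics are computed on dL = L_t - L_(first frame) in subunits,
converting from micrometres first when necessary, so the Fano factor is always
reported in subunit units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import TrajectoryEnsemble

__all__ = [
    "FanoSeries",
    "SampleSizeEstimate",
    "empirical_moments",
    "fano_series",
    "required_sample_size",
]

_BOOT_CHUNK = 100  # bootstrap replicates per vectorized block (memory bound)


@dataclass(frozen=True)
class FanoSeries:
    """Time-resolved Fano factor of an ensemble with bootstrap bounds.

    ``fano`` is variance/mean of dL in subunits; NaN marks time points where
    the mean vanishes and the ratio is undefined.  ``ci_low``/``ci_high`` are
    percentile-bootstrap bounds at level ``ci_level``.
    """

    times: np.ndarray
    mean: np.ndarray
    variance: np.ndarray
    fano: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_boot: int
    n_filaments: int
    ci_level: float = 0.95

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "mean": self.mean,
                "variance": self.variance,
                "fano": self.fano,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class SampleSizeEstimate:
    """Filament count needed for a target relative error in the Fano factor.

    N = (1/eps^2) * (2 + 0.0027 * F / mu) with the Fano factor F in subunits
    and the mean growth mu in micrometres; ``dominant_term_only`` keeps only
    the leading constant 2 in the bracket (appropriate when 0.0027*F/mu << 2).
    """

    epsilon: float
    fano_subunits: float
    mean_growth_um: float
    n_required: float
    dominant_term_only: bool

    @property
    def n_ceiling(self) -> int:
        return math.ceil(self.n_required)


def _frame_indices(ensemble: TrajectoryEnsemble, at_times) -> np.ndarray:
    if at_times is None:
        return np.arange(ensemble.frame_times.size)
    at_times = np.atleast_1d(np.asarray(at_times, dtype=float))
    idx = np.searchsorted(ensemble.frame_times, at_times)
    idx = np.clip(idx, 0, ensemble.frame_times.size - 1)
    # accept the neighbour on either side within float tolerance
    left = np.clip(idx - 1, 0, None)
    use_left = np.abs(ensemble.frame_times[left] - at_times) < np.abs(
        ensemble.frame_times[idx] - at_times
    )
    idx = np.where(use_left, left, idx)
    if not np.allclose(ensemble.frame_times[idx], at_times, rtol=0, atol=1e-9):
        missing = at_times[~np.isclose(ensemble.frame_times[idx], at_times, atol=1e-9)]
        raise ValueError(f"requested times not on the frame grid: {missing}")
    return idx


def empirical_moments(ensemble: TrajectoryEnsemble, at_times=None) -> pd.DataFrame:
    """Cross-filament mean and unbiased variance of dL (subunits) per time.

    Requires at least two filaments for the variance (n-1 denominator).
    """
    if ensemble.n_filaments < 2:
        raise ValueError("variance needs at least 2 filaments")
    idx = _frame_indices(ensemble, at_times)
    dL = ensemble.delta_lengths_subunits()[:, idx]
    return pd.DataFrame(
        {
            "time_s": ensemble.frame_times[idx],
            "mean": dL.mean(axis=0),
            "variance": dL.var(axis=0, ddof=1),
        }
    )


def _fano_of(dL: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mean, variance and Fano along filament axis; NaN where mean ~ 0."""
    mean = dL.mean(axis=-2)
    var = dL.var(axis=-2, ddof=1)
    fano = np.full_like(mean, np.nan)
    defined = np.abs(mean) > 1e-12 * np.maximum(1.0, var)
    np.divide(var, mean, out=fano, where=defined)
    return mean, var, fano


def fano_series(
    ensemble: TrajectoryEnsemble,
    at_times=None,
    n_boot: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> FanoSeries:
    """Time-resolved Fano factor with a percentile-bootstrap confidence band.

    Whole filaments are resampled with replacement ``n_boot`` times; at each
    time point the band is the percentile interval of the resampled Fano
    values.  Deterministic given ``seed``.
    """
    if ensemble.n_filaments < 2:
        raise ValueError("Fano factor needs at least 2 filaments")
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    idx = _frame_indices(ensemble, at_times)
    dL = ensemble.delta_lengths_subunits()[:, idx]
    n = ensemble.n_filaments
    mean, var, fano = _fano_of(dL)

    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, idx.size))
    done = 0
    while done < n_boot:
        k = min(_BOOT_CHUNK, n_boot - done)
        resample = rng.integers(0, n, size=(k, n))
        _, _, boot_f = _fano_of(dL[resample, :])
        boot[done : done + k] = boot_f
        done += k
    alpha = (1.0 - ci_level) / 2.0
    with np.errstate(invalid="ignore"):
        all_nan = np.all(np.isnan(boot), axis=0)
        ci_low = np.full(idx.size, np.nan)
        ci_high = np.full(idx.size, np.nan)
        if not all_nan.all():
            cols = ~all_nan
            ci_low[cols] = np.nanpercentile(boot[:, cols], 100 * alpha, axis=0)
            ci_high[cols] = np.nanpercentile(boot[:, cols], 100 * (1 - alpha), axis=0)
    return FanoSeries(
        times=ensemble.frame_times[idx],
        mean=mean,
        variance=var,
        fano=fano,
        ci_low=ci_low,
        ci_high=ci_high,
        n_boot=n_boot,
        n_filaments=n,
        ci_level=ci_level,
    )


def required_sample_size(
    epsilon: float,
    fano_subunits: float,
    mean_growth_um: float,
    dominant_term_only: bool = False,
) -> SampleSizeEstimate:
    """Filaments needed for relative error ``epsilon`` in the Fano factor.

    Evaluates N = (1/eps^2) * (2 + 0.0027 * F / mu); with
    ``dominant_term_only`` the bracket is reduced to its leading constant 2.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    if mean_growth_um <= 0:
        raise ValueError("mean_growth_um must be > 0")
    if fano_subunits < 0:
        raise ValueError("fano_subunits must be >= 0")
    bracket = 2.0 if dominant_term_only else 2.0 + 0.0027 * fano_subunits / mean_growth_um
    n = bracket / epsilon**2
    return SampleSizeEstimate(
        epsilon=epsilon,
        fano_subunits=fano_subunits,
        mean_growth_um=mean_growth_um,
        n_required=n,
        dominant_term_only=dominant_term_only,
    )
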