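"""Exact stochastic simulation of filament length trajectories.

Two layers:

* :func:`simulate_trajectory` — the full event-driven SSA for a single
  filament: in state i, competing exponential clocks for every outgoing
  switch (rate k_ji) and for a unit length step (+1 at rate r_i in a
  polymerizing state, -1 at rate gamma_i in a depolymerizing one).  Returns
  the complete event path.

* :func:`simulate_ensemble` — exact sampling of many filaments at a fixed
  frame grid.  Per filament the switching path is simulated event-by-event;
  conditional on that path, the unit length steps form an inhomogeneous
  Poisson process that is piecewise homogeneous, so the step counts on the
  disjoint constant-state intervals between consecutive frame/switch
  breakpoints are independent Poisson variates and are drawn directly.  The
  sampled lengths have exactly the joint law of the event path evaluated at
  the frame times, at a small fraction of the cost of enumerating every
  subunit addition.

Reproducibility: a single integer seed fully determines an ensemble;
per-filament streams are spawned from a ``numpy`` ``SeedSequence``, never
shared.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .model import DEPOLYMERIZING, KineticModel
from .moments import stationary_distribution
from .reference import SUBUNIT_LENGTH_UM

__all__ = [
    "EventPath",
    "TrajectoryEnsemble",
    "simulate_trajectory",
    "simulate_ensemble",
    "to_microscopy_like",
]


@dataclass(frozen=True)
class EventPath:
    """Exact event path of one filament: piecewise-constant (state, dL).

    ``times[k]`` is the time of the k-th event (``times[0] = 0``);
    ``lengths[k]`` and ``states[k]`` hold the cumulative length change and
    state index immediately after it.  ``absorbed`` flags a halt in a state
    with no outgoing rate at all (zero step rate and no exits), which is valid
    absorbing behaviour, not an error.
    """

    times: np.ndarray
    lengths: np.ndarray
    states: np.ndarray
    duration: float
    absorbed: bool = False

    def sample(self, at_times) -> tuple[np.ndarray, np.ndarray]:
        """Length change and state at given times (piecewise-constant)."""
        at_times = np.asarray(at_times, dtype=float)
        if np.any(at_times < 0) or np.any(at_times > self.duration):
            raise ValueError("sample times must lie within [0, duration]")
        idx = np.searchsorted(self.times, at_times, side="right") - 1
        return self.lengths[idx], self.states[idx]


@dataclass(frozen=True)
class TrajectoryEnsemble:
    """Per-filament length change sampled on a common frame grid.

    ``lengths[f, k]`` is filament f's length at ``frame_times[k]`` — the
    cumulative change in subunits since the first frame when
    ``unit == "subunits"``, or an absolute length in micrometres after
    :func:`to_microscopy_like`.  ``states`` (optional) records the state index
    at each frame.
    """

    frame_times: np.ndarray
    lengths: np.ndarray
    unit: str = "subunits"
    states: np.ndarray | None = None
    seed: int | None = None
    model_fingerprint: str | None = None
    subunit_length_um: float = SUBUNIT_LENGTH_UM

    def __post_init__(self) -> None:
        ft = np.asarray(self.frame_times, dtype=float)
        L = np.asarray(self.lengths, dtype=float)
        if ft.ndim != 1 or np.any(np.diff(ft) <= 0):
            raise ValueError("frame_times must be strictly increasing 1-D")
        if L.ndim != 2 or L.shape[1] != ft.size:
            raise ValueError(
                f"lengths shape {L.shape} incompatible with {ft.size} frames"
            )
        if self.unit not in ("subunits", "um"):
            raise ValueError(f"unit must be 'subunits' or 'um', got {self.unit!r}")
        object.__setattr__(self, "frame_times", ft)
        object.__setattr__(self, "lengths", L)

    @property
    def n_filaments(self) -> int:
        return self.lengths.shape[0]

    def delta_lengths_subunits(self) -> np.ndarray:
        """Length change since the first frame, in subunits.

        Converts from micrometres if needed and subtracts the first-frame
        value per filament, so statistics are always on dL = L_t - L_0.
        """
        L = self.lengths
        if self.unit == "um":
            L = L / self.subunit_length_um
        return L - L[:, [0]]

    # -- long-format CSV I/O ---------------------------------------------

    def to_dataframe(self) -> pd.DataFrame:
        n, m = self.lengths.shape
        return pd.DataFrame(
            {
                "filament_id": np.repeat(np.arange(n), m),
                "time_s": np.tile(self.frame_times, n),
                "length": self.lengths.ravel(),
                "unit": self.unit,
            }
        )

    def to_csv(self, path) -> None:
        """Write long-format CSV plus a JSON provenance sidecar."""
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        sidecar = {
            "n_filaments": int(self.n_filaments),
            "n_frames": int(self.frame_times.size),
            "unit": self.unit,
            "seed": self.seed,
            "model_fingerprint": self.model_fingerprint,
            "subunit_length_um": self.subunit_length_um,
        }
        path.with_suffix(path.suffix + ".meta.json").write_text(
            json.dumps(sidecar, indent=2)
        )

    @classmethod
    def from_csv(cls, path) -> "TrajectoryEnsemble":
        """Read the long-format CSV written by :meth:`to_csv` (or external
        data in the same schema: filament_id, time_s, length, unit)."""
        df = pd.read_csv(path)
        required = {"filament_id", "time_s", "length", "unit"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"trajectory CSV missing columns {sorted(missing)}")
        units = df["unit"].unique()
        if len(units) != 1:
            raise ValueError(f"trajectory CSV mixes units {sorted(units)}")
        wide = df.pivot(index="filament_id", columns="time_s", values="length")
        if wide.isna().any().any():
            raise ValueError("trajectory CSV is not a complete filament x time grid")
        meta_path = Path(path).with_suffix(Path(path).suffix + ".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        return cls(
            frame_times=wide.columns.to_numpy(dtype=float),
            lengths=wide.to_numpy(dtype=float),
            unit=str(units[0]),
            seed=meta.get("seed"),
            model_fingerprint=meta.get("model_fingerprint"),
            subunit_length_um=meta.get("subunit_length_um", SUBUNIT_LENGTH_UM),
        )


# ---------------------------------------------------------------------------
# single-trajectory SSA
# ---------------------------------------------------------------------------


def simulate_trajectory(
    model: KineticModel,
    initial_state: int,
    duration: float,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    max_events: int = 50_000_000,
) -> EventPath:
    """Exact SSA realization of the joint (state, length) jump process."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    if not 0 <= initial_state < model.n_states:
        raise ValueError(f"initial_state {initial_state} out of range")
    if rng is None:
        rng = np.random.default_rng(seed)
    K = model.generator
    step_rates = model.step_rates
    signs = np.where(
        np.array([s.state_class == DEPOLYMERIZING for s in model.states]), -1, 1
    )
    out_rates = -np.diag(K)

    times = [0.0]
    lengths = [0]
    states = [initial_state]
    t, s, length = 0.0, initial_state, 0
    absorbed = False
    for _ in range(max_events):
        total = step_rates[s] + out_rates[s]
        if total == 0.0:
            absorbed = True
            break
        t += rng.exponential(1.0 / total)
        if t >= duration:
            break
        if rng.random() * total < step_rates[s]:
            length += signs[s]
        else:
            # pick destination proportional to the off-diagonal column rates
            u = rng.random() * out_rates[s]
            acc = 0.0
            for dest in range(model.n_states):
                if dest == s:
                    continue
                acc += K[dest, s]
                if u < acc:
                    s = dest
                    break
        times.append(t)
        lengths.append(length)
        states.append(s)
    else:
        raise RuntimeError(f"exceeded max_events={max_events} before duration")
    return EventPath(
        times=np.array(times),
        lengths=np.array(lengths, dtype=float),
        states=np.array(states),
        duration=float(duration),
        absorbed=absorbed,
    )


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------


def _switching_path(
    model: KineticModel, s0: int, duration: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Event times and visited states of the switching chain alone."""
    K = model.generator
    out_rates = -np.diag(K)
    times = [0.0]
    states = [s0]
    t, s = 0.0, s0
    while True:
        if out_rates[s] == 0.0:
            break
        t += rng.exponential(1.0 / out_rates[s])
        if t >= duration:
            break
        u = rng.random() * out_rates[s]
        acc = 0.0
        for dest in range(model.n_states):
            if dest == s:
                continue
            acc += K[dest, s]
            if u < acc:
                s = dest
                break
        times.append(t)
        states.append(s)
    return np.array(times), np.array(states)


def _sample_filament(
    model: KineticModel,
    s0: int,
    frame_times: np.ndarray,
    rng: np.random.Generator,
    signed_rates: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Exact lengths and states of one filament at the frame times."""
    duration = frame_times[-1]
    switch_t, switch_s = _switching_path(model, s0, duration, rng)
    breaks = np.union1d(frame_times, switch_t)
    # state on each interval [breaks[k], breaks[k+1])
    seg_state = switch_s[np.searchsorted(switch_t, breaks[:-1], side="right") - 1]
    seg_rate = signed_rates[seg_state]
    lam = np.abs(seg_rate) * np.diff(breaks)
    counts = rng.poisson(lam) * np.sign(seg_rate)
    cum = np.concatenate([[0.0], np.cumsum(counts)])
    frame_idx = np.searchsorted(breaks, frame_times)
    lengths = cum[frame_idx]
    frame_states = switch_s[np.searchsorted(switch_t, frame_times, side="right") - 1]
    return lengths, frame_states


def simulate_ensemble(
    model: KineticModel,
    initial: int | str,
    n_filaments: int,
    frame_times,
    seed: int,
    record_states: bool = True,
) -> TrajectoryEnsemble:
    """Ensemble of independent filaments sampled at ``frame_times``.

    ``initial`` is a state index, a state label, or ``"stationary"``, which
    draws each filament's initial state from the stationary distribution —
    the protocol behind long-time window statistics.  The first frame must be
    at t = 0 so that lengths are changes since observation start.
    """
    if n_filaments < 1:
        raise ValueError("n_filaments must be >= 1")
    frame_times = np.asarray(frame_times, dtype=float)
    if frame_times.ndim != 1 or frame_times.size < 2 or np.any(np.diff(frame_times) <= 0):
        raise ValueError("frame_times must be strictly increasing with >= 2 frames")
    if frame_times[0] != 0.0:
        raise ValueError("frame_times must start at 0 (lengths are dL since t=0)")

    pi = None
    if isinstance(initial, str) and initial == "stationary":
        pi = stationary_distribution(model)
    elif isinstance(initial, str):
        initial = model.index(initial)
    elif not 0 <= int(initial) < model.n_states:
        raise ValueError(f"initial state {initial} out of range")

    signed_rates = model.signed_rates
    children = np.random.SeedSequence(seed).spawn(n_filaments)
    lengths = np.empty((n_filaments, frame_times.size))
    states = np.empty((n_filaments, frame_times.size), dtype=np.int64)
    for f in range(n_filaments):
        rng = np.random.default_rng(children[f])
        s0 = int(rng.choice(model.n_states, p=pi)) if pi is not None else int(initial)
        lengths[f], states[f] = _sample_filament(
            model, s0, frame_times, rng, signed_rates
        )
    return TrajectoryEnsemble(
        frame_times=frame_times,
        lengths=lengths,
        unit="subunits",
        states=states if record_states else None,
        seed=seed,
        model_fingerprint=model.fingerprint(),
    )


def to_microscopy_like(
    ensemble: TrajectoryEnsemble,
    subunit_length_um: float = SUBUNIT_LENGTH_UM,
    noise_sd_um: float = 0.0,
    initial_length_um: float = 0.0,
    seed: int | None = None,
) -> TrajectoryEnsemble:
    """Convert a subunit ensemble to micrometre traces as a microscope reports
    them: linear unit conversion, an optional common initial length, and
    optional i.i.d. Gaussian per-frame measurement noise (an emulation knob;
    off by default)."""
    if ensemble.unit != "subunits":
        raise ValueError("expected an ensemble in subunits")
    if noise_sd_um < 0:
        raise ValueError("noise_sd_um must be >= 0")
    lengths_um = initial_length_um + ensemble.lengths * subunit_length_um
    if noise_sd_um > 0:
        rng = np.random.default_rng(seed)
        lengths_um = lengths_um + rng.normal(0.0, noise_sd_um, size=lengths_um.shape)
    return replace(
        ensemble,
        lengths=lengths_um,
        unit="um",
        subunit_length_um=subunit_length_um,
    )
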