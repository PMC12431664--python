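"""N-state kinetic models of actin filament length regulation.

A filament stochastically switches between discrete states, each representing a
combination of actin-binding proteins (ABPs) bound to it.  Every state either
polymerizes (adds subunits at rate ``r_i``) or depolymerizes (removes subunits
at rate ``gamma_j``); capped states are polymerizing states with rate exactly
zero.  Switching is a continuous-time Markov chain with generator ``K`` whose
off-diagonal entry ``K[i, j]`` is the rate of the ``j -> i`` transition and
whose columns sum to zero, so probability is conserved.

The module provides the :class:`KineticModel` container, validated builders for
the canonical one-, two-, three- and four-state regulatory schemes (elongator,
capper, competitive and simultaneous binding), a fully general
:func:`build_custom`, and lossless YAML/JSON config round-tripping.

Units: rates in s^-1 or subunits/s, on-rate constants in uM^-1 s^-1,
concentrations in uM.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import yaml
from scipy.sparse import csgraph, csr_matrix

POLYMERIZING = "polymerizing"
DEPOLYMERIZING = "depolymerizing"

_COLUMN_SUM_TOL = 1e-12


class ModelValidationError(ValueError):
    """Raised when a state set or generator violates a model invariant."""


@dataclass(frozen=True)
class StateSpec:
    """One filament state: a label, a class, and a length-step rate.

    ``rate`` is the polymerization rate r_i (subunits/s) for polymerizing
    states or the depolymerization rate gamma_j for depolymerizing states.
    A capped state is a polymerizing state with ``rate == 0``.
    """

    label: str
    state_class: str
    rate: float

    def __post_init__(self) -> None:
        if self.state_class not in (POLYMERIZING, DEPOLYMERIZING):
            raise ModelValidationError(
                f"state_class must be {POLYMERIZING!r} or {DEPOLYMERIZING!r}, "
                f"got {self.state_class!r}"
            )
        if not np.isfinite(self.rate) or self.rate < 0:
            raise ModelValidationError(
                f"state {self.label!r}: rate must be finite and >= 0, got {self.rate}"
            )
        if not self.label:
            raise ModelValidationError("state label must be a non-empty string")


@dataclass(frozen=True)
class RegulatorKinetics:
    """Concentration-dependent binding kinetics of one regulator.

    The effective (pseudo-first-order) on-rate is
    ``on_rate = on_rate_constant * concentration`` and scales linearly with
    concentration; ``off_rate`` is concentration independent.

    Units: ``on_rate_constant`` uM^-1 s^-1, ``concentration`` uM,
    ``off_rate`` s^-1.
    """

    name: str
    on_rate_constant: float
    concentration: float
    off_rate: float

    def __post_init__(self) -> None:
        for attr in ("on_rate_constant", "concentration", "off_rate"):
            v = getattr(self, attr)
            if not np.isfinite(v) or v < 0:
                raise ModelValidationError(
                    f"regulator {self.name!r}: {attr} must be finite and >= 0, got {v}"
                )

    @property
    def on_rate(self) -> float:
        """Effective binding rate k+ = k~+ [X], in s^-1."""
        return self.on_rate_constant * self.concentration

    def at_concentration(self, concentration_uM: float) -> "RegulatorKinetics":
        """Same kinetic constants at a different concentration (uM)."""
        return replace(self, concentration=concentration_uM)


@dataclass(frozen=True)
class KineticModel:
    """An N-state switching model of filament length dynamics.

    Attributes
    ----------
    states : tuple of StateSpec
        Ordered state set; the ordering indexes every matrix and vector.
    generator : ndarray, shape (N, N)
        CTMC generator: ``generator[i, j]`` (i != j) is the switching rate
        from state j to state i; diagonal entries are the negated total
        outflow of each column, so columns sum to zero.
    """

    states: tuple[StateSpec, ...]
    generator: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        states = tuple(self.states)
        object.__setattr__(self, "states", states)
        if len(states) < 1:
            raise ModelValidationError("a model needs at least one state")
        labels = [s.label for s in states]
        if len(set(labels)) != len(labels):
            raise ModelValidationError(f"duplicate state labels in {labels}")
        K = np.array(self.generator, dtype=float)
        n = len(states)
        if K.shape != (n, n):
            raise ModelValidationError(
                f"generator shape {K.shape} does not match {n} states"
            )
        off = K.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off < 0):
            raise ModelValidationError("off-diagonal switching rates must be >= 0")
        scale = max(1.0, float(np.abs(K).max(initial=0.0)))
        colsums = K.sum(axis=0)
        if np.any(np.abs(colsums) > _COLUMN_SUM_TOL * scale):
            raise ModelValidationError(
                f"generator columns must sum to 0, got column sums {colsums}"
            )
        K.setflags(write=False)
        object.__setattr__(self, "generator", K)

    # -- basic queries ----------------------------------------------------

    @property
    def n_states(self) -> int:
        return len(self.states)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(s.label for s in self.states)

    def index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise KeyError(f"no state labelled {label!r}; states are {self.labels}")

    @property
    def step_rates(self) -> np.ndarray:
        """Magnitude of the length-step rate of every state (r_i or gamma_j)."""
        return np.array([s.rate for s in self.states])

    @property
    def signed_rates(self) -> np.ndarray:
        """+r_i for polymerizing states, -gamma_j for depolymerizing states."""
        sign = np.array(
            [1.0 if s.state_class == POLYMERIZING else -1.0 for s in self.states]
        )
        return sign * self.step_rates

    @property
    def rate_up(self) -> np.ndarray:
        """Polymerization part of the diagonal rate matrix (vector of r_i)."""
        return np.array(
            [s.rate if s.state_class == POLYMERIZING else 0.0 for s in self.states]
        )

    @property
    def rate_down(self) -> np.ndarray:
        """Depolymerization part of the diagonal rate matrix (vector of gamma_j)."""
        return np.array(
            [s.rate if s.state_class == DEPOLYMERIZING else 0.0 for s in self.states]
        )

    def is_irreducible(self) -> bool:
        """True if the switching graph has a single strongly connected class."""
        if self.n_states == 1:
            return True
        off = np.array(self.generator)
        np.fill_diagonal(off, 0.0)
        ncomp, _ = csgraph.connected_components(
            csr_matrix(off.T != 0), directed=True, connection="strong"
        )
        return ncomp == 1

    def n_closed_classes(self) -> int:
        """Number of closed (recurrent) communicating classes.

        A unique stationary distribution exists iff this is 1; states outside
        the closed class (e.g. the bound state at zero regulator
        concentration) are transient and carry no stationary mass.
        """
        if self.n_states == 1:
            return 1
        off = np.array(self.generator)
        np.fill_diagonal(off, 0.0)
        adj = off.T != 0  # adj[i, j]: edge i -> j
        ncomp, labels = csgraph.connected_components(
            csr_matrix(adj), directed=True, connection="strong"
        )
        closed = 0
        src, dst = np.nonzero(adj)
        for c in range(ncomp):
            members = labels == c
            leaves = np.any(members[src] & (labels[dst] != c))
            closed += not leaves
        return closed

    def fingerprint(self) -> str:
        """Stable hash of states and rates, for provenance sidecars."""
        h = hashlib.sha256()
        for s in self.states:
            h.update(f"{s.label}|{s.state_class}|{s.rate!r};".encode())
        h.update(np.ascontiguousarray(self.generator).tobytes())
        return h.hexdigest()[:16]

    # -- config round-trip ------------------------------------------------

    def to_config(self) -> dict:
        """Plain-dict form (states + off-diagonal transitions); lossless."""
        transitions = []
        for j in range(self.n_states):
            for i in range(self.n_states):
                if i != j and self.generator[i, j] != 0.0:
                    transitions.append(
                        {
                            "from": self.states[j].label,
                            "to": self.states[i].label,
                            "rate": float(self.generator[i, j]),
                        }
                    )
        return {
            "states": [
                {"label": s.label, "class": s.state_class, "rate": float(s.rate)}
                for s in self.states
            ],
            "transitions": transitions,
        }

    @classmethod
    def from_config(cls, config: dict) -> "KineticModel":
        try:
            states = [
                StateSpec(d["label"], d["class"], float(d["rate"]))
                for d in config["states"]
            ]
            transitions = [
                (d["from"], d["to"], float(d["rate"]))
                for d in config.get("transitions", [])
            ]
        except (KeyError, TypeError) as err:
            raise ModelValidationError(f"malformed model config: {err}") from err
        return build_custom(states, transitions)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_config(), sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "KineticModel":
        return cls.from_config(yaml.safe_load(text))

    def to_json(self) -> str:
        return json.dumps(self.to_config(), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "KineticModel":
        return cls.from_config(json.loads(text))


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------


def _assemble(
    states: Sequence[StateSpec],
    transitions: Sequence[tuple[str, str, float]],
) -> KineticModel:
    labels = [s.label for s in states]
    if len(set(labels)) != len(labels):
        raise ModelValidationError(f"duplicate state labels in {labels}")
    n = len(states)
    K = np.zeros((n, n))
    for src, dst, rate in transitions:
        if src not in labels:
            raise ModelValidationError(f"unknown source state {src!r} in transition")
        if dst not in labels:
            raise ModelValidationError(f"unknown target state {dst!r} in transition")
        if not np.isfinite(rate) or rate < 0:
            raise ModelValidationError(
                f"transition {src!r}->{dst!r}: rate must be finite and >= 0, got {rate}"
            )
        K[labels.index(dst), labels.index(src)] += rate
    K[np.diag_indices(n)] -= K.sum(axis=0)
    return KineticModel(states=tuple(states), generator=K)


def build_one_state(rate: float, state_class: str = POLYMERIZING) -> KineticModel:
    """Single-state model: pure Poisson growth (or shrinkage) at ``rate``."""
    return _assemble([StateSpec("S", state_class, rate)], [])


def build_two_state_elongator(
    r1: float, r2: float, elongator: RegulatorKinetics
) -> KineticModel:
    """Bare (B, rate r1) <-> elongator-bound (BF, rate r2) model.

    B gains the elongator at ``k_F+ = k~_F+ [F]`` and loses it at ``k_F-``.
    """
    states = [
        StateSpec("B", POLYMERIZING, r1),
        StateSpec("BF", POLYMERIZING, r2),
    ]
    transitions = [
        ("B", "BF", elongator.on_rate),
        ("BF", "B", elongator.off_rate),
    ]
    return _assemble(states, transitions)


def build_two_state_capper(r1: float, capper: RegulatorKinetics) -> KineticModel:
    """Bare (B, rate r1) <-> capper-bound (BC, rate 0) model.

    The capped state is a polymerizing state with rate zero by convention.
    """
    states = [
        StateSpec("B", POLYMERIZING, r1),
        StateSpec("BC", POLYMERIZING, 0.0),
    ]
    transitions = [
        ("B", "BC", capper.on_rate),
        ("BC", "B", capper.off_rate),
    ]
    return _assemble(states, transitions)


def build_competitive(
    r1: float,
    r2: float,
    elongator: RegulatorKinetics,
    capper: RegulatorKinetics,
) -> KineticModel:
    """Three-state competitive-binding model: elongator and capper exclude
    each other at the filament end.

    States: B (rate r1), BF (rate r2), BC (rate 0); transitions B<->BF and
    B<->BC only — no direct BF<->BC exchange.
    """
    states = [
        StateSpec("B", POLYMERIZING, r1),
        StateSpec("BF", POLYMERIZING, r2),
        StateSpec("BC", POLYMERIZING, 0.0),
    ]
    transitions = [
        ("B", "BF", elongator.on_rate),
        ("BF", "B", elongator.off_rate),
        ("B", "BC", capper.on_rate),
        ("BC", "B", capper.off_rate),
    ]
    return _assemble(states, transitions)


def build_simultaneous(
    r1: float,
    r2: float,
    elongator: RegulatorKinetics,
    capper: RegulatorKinetics,
    elongator_secondary: RegulatorKinetics,
    capper_secondary: RegulatorKinetics,
) -> KineticModel:
    """Four-state simultaneous-binding model: both regulators can co-occupy
    the filament end.

    States: B (rate r1), BF (rate r2), BC (rate 0), dual-bound BFC (rate 0).
    ``capper_secondary`` governs capper binding to the elongator-bound end
    (BF <-> BFC) and ``elongator_secondary`` governs elongator binding to the
    capped end (BC <-> BFC); these "primed" legs typically have kinetic
    constants different from the bare-end legs.
    """
    states = [
        StateSpec("B", POLYMERIZING, r1),
        StateSpec("BF", POLYMERIZING, r2),
        StateSpec("BC", POLYMERIZING, 0.0),
        StateSpec("BFC", POLYMERIZING, 0.0),
    ]
    transitions = [
        ("B", "BF", elongator.on_rate),
        ("BF", "B", elongator.off_rate),
        ("B", "BC", capper.on_rate),
        ("BC", "B", capper.off_rate),
        ("BF", "BFC", capper_secondary.on_rate),
        ("BFC", "BF", capper_secondary.off_rate),
        ("BC", "BFC", elongator_secondary.on_rate),
        ("BFC", "BC", elongator_secondary.off_rate),
    ]
    return _assemble(states, transitions)


def build_custom(
    states: Sequence[StateSpec],
    transitions: Sequence[tuple[str, str, float]],
) -> KineticModel:
    """Arbitrary N-state model from a state list and labelled transitions.

    Covers any regulatory architecture (e.g. an elongator + capper +
    depolymerase scheme) beyond the canonical builders.
    """
    return _assemble(states, transitions)
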