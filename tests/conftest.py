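import numpy as np
import pytest

import filament_kinetics as fk
from filament_kinetics import reference as ref


@pytest.fixture
def one_state_model():
    return fk.build_one_state(ref.BARE_RATE)


@pytest.fixture
def elongator_model():
    # formin at 1 nM, the canonical two-state growth-switching model
    return fk.build_two_state_elongator(
        ref.BARE_RATE, ref.FORMIN_BOUND_RATE, ref.formin(1e-3)
    )


@pytest.fixture
def capper_model():
    return fk.build_two_state_capper(ref.BARE_RATE, ref.capping_protein(1e-2))


@pytest.fixture
def competitive_model():
    return fk.build_competitive(
        ref.BARE_RATE, ref.FORMIN_BOUND_RATE, ref.formin(1e-2), ref.capping_protein(1e-2)
    )


@pytest.fixture
def simultaneous_model():
    return fk.build_simultaneous(
        ref.BARE_RATE,
        ref.FORMIN_BOUND_RATE,
        ref.formin(1e-2),
        ref.capping_protein(1e-2),
        ref.formin_primed(1e-2),
        ref.capping_protein_primed(1e-2),
    )


@pytest.fixture
def random_walk_model():
    # balanced polymerizing/depolymerizing pair with symmetric fast switching
    states = [
        fk.StateSpec("up", fk.POLYMERIZING, 6.0),
        fk.StateSpec("down", fk.DEPOLYMERIZING, 6.0),
    ]
    transitions = [("up", "down", 1.0), ("down", "up", 1.0)]
    return fk.build_custom(states, transitions)


def monte_carlo_errors(samples: np.ndarray) -> tuple[float, float]:
    """Standard errors of the sample mean and of the unbiased variance."""
    n = samples.size
    mean = samples.mean()
    var = samples.var(ddof=1)
    se_mean = samples.std(ddof=1) / np.sqrt(n)
    m4 = np.mean((samples - mean) ** 4)
    se_var = np.sqrt(max(m4 - var**2, 0.0) / n)
    return se_mean, se_var
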