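"""Builders, generator invariants and config round-tripping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import filament_kinetics as fk
from filament_kinetics import reference as ref
from filament_kinetics.model import ModelValidationError


def _assert_generator_invariants(model):
    K = model.generator
    off = K.copy()
    np.fill_diagonal(off, 0.0)
    assert np.all(off >= 0)
    assert np.max(np.abs(K.sum(axis=0))) <= 1e-12 * max(1.0, np.abs(K).max())


ALL_BUILDERS = {
    "one_state": lambda: fk.build_one_state(6.0),
    "elongator": lambda: fk.build_two_state_elongator(6, 30, ref.formin(1e-3)),
    "capper": lambda: fk.build_two_state_capper(6, ref.capping_protein(1e-2)),
    "competitive": lambda: fk.build_competitive(
        6, 30, ref.formin(1e-2), ref.capping_protein(1e-2)
    ),
    "simultaneous": lambda: fk.build_simultaneous(
        6, 30, ref.formin(1e-2), ref.capping_protein(1e-2),
        ref.formin_primed(1e-2), ref.capping_protein_primed(1e-2),
    ),
}


@pytest.mark.parametrize("name", sorted(ALL_BUILDERS))
def test_builder_generator_invariants(name):
    """Every builder emits nonnegative off-diagonals and zero column sums."""
    _assert_generator_invariants(ALL_BUILDERS[name]())


def test_one_state_zero_generator():
    m = fk.build_one_state(6.0)
    assert m.n_states == 1
    assert m.generator.shape == (1, 1) and m.generator[0, 0] == 0.0
    # a permanently capped filament is a valid zero-rate polymerizing state
    capped = fk.build_one_state(0.0)
    assert capped.states[0].rate == 0.0


def test_one_state_rejects_negative_rate():
    with pytest.raises(ModelValidationError):
        fk.build_one_state(-1.0)


def test_elongator_off_diagonals_at_zero_concentration():
    """At [F]=0 the only nonzero off-diagonal is the unbinding leg."""
    m = fk.build_two_state_elongator(6, 30, ref.formin(0.0))
    assert m.generator[1, 0] == 0.0
    assert m.generator[0, 1] == pytest.approx(8.1e-5)
    pi = fk.stationary_distribution(m)
    assert pi[m.index("B")] == pytest.approx(1.0, abs=1e-12)


def test_effective_on_rate_linear_in_concentration():
    reg = ref.formin(1e-3)
    assert reg.at_concentration(2e-3).on_rate == pytest.approx(2 * reg.on_rate, rel=0)


def test_capper_effective_on_rate_and_capped_rate():
    m = fk.build_two_state_capper(6, ref.capping_protein(0.01))
    assert m.generator[m.index("BC"), m.index("B")] == pytest.approx(0.128)
    assert m.states[m.index("BC")].rate == 0.0
    assert m.states[m.index("BC")].state_class == fk.POLYMERIZING


def test_competitive_topology():
    """Mutually exclusive binding: exactly 4 nonzero off-diagonal entries."""
    m = ALL_BUILDERS["competitive"]()
    off = m.generator.copy()
    np.fill_diagonal(off, 0.0)
    assert np.count_nonzero(off) == 4
    assert off[m.index("BC"), m.index("BF")] == 0.0
    assert off[m.index("BF"), m.index("BC")] == 0.0


def test_competitive_stationary_matches_nullspace_solve(competitive_model):
    """Stationary occupancies agree with a dense null-space oracle."""
    pi = fk.stationary_distribution(competitive_model)
    K = competitive_model.generator
    w, v = np.linalg.eig(K)
    k = np.argmin(np.abs(w))
    oracle = np.real(v[:, k])
    oracle = oracle / oracle.sum()
    np.testing.assert_allclose(pi, oracle, atol=1e-10)


def test_simultaneous_matches_hand_written_generator():
    """The 4-state scheme equals the hand-transcribed generator elementwise."""
    F, C = 1e-2, 1e-2
    m = fk.build_simultaneous(
        6, 30, ref.formin(F), ref.capping_protein(C),
        ref.formin_primed(F), ref.capping_protein_primed(C),
    )
    kfp, kfm = 29.1 * F, 8.1e-5
    kcp, kcm = 12.8 * C, 2.0e-4
    kfp2, kfm2 = 1.6 * F, 6.2e-3
    kcp2, kcm2 = 0.21 * C, 6.2e-3
    # order: B, BF, BC, BFC
    K = np.array([
        [-(kfp + kcp), kfm,               kcm,              0.0],
        [kfp,          -(kfm + kcp2),     0.0,              kcm2],
        [kcp,          0.0,               -(kcm + kfp2),    kfm2],
        [0.0,          kcp2,              kfp2,             -(kfm2 + kcm2)],
    ])
    np.testing.assert_allclose(m.generator, K, rtol=0, atol=0)
    # primed constants live on the dual-bound legs
    assert m.generator[m.index("BFC"), m.index("BF")] == pytest.approx(0.21 * C)
    assert m.generator[m.index("BFC"), m.index("BC")] == pytest.approx(1.6 * F)


@pytest.mark.parametrize(
    "reduced, full",
    [
        (
            lambda F: fk.build_two_state_elongator(6, 30, ref.formin(F)),
            lambda F: fk.build_competitive(
                6, 30, ref.formin(F), ref.capping_protein(0.0)
            ),
        ),
        (
            lambda C: fk.build_two_state_capper(6, ref.capping_protein(C)),
            lambda C: fk.build_competitive(
                6, 30, ref.formin(0.0), ref.capping_protein(C)
            ),
        ),
    ],
)
def test_competitive_reduces_to_two_state(reduced, full):
    """With one regulator absent, the 3-state model reproduces the matching
    2-state stationary occupancies and long-time mean."""
    x = 1e-3
    m2, m3 = reduced(x), full(x)
    pi2, pi3 = fk.stationary_distribution(m2), fk.stationary_distribution(m3)
    shared = [m3.index(lbl) for lbl in m2.labels]
    np.testing.assert_allclose(pi3[shared], pi2, atol=1e-10)
    mu2 = fk.longtime_moment(m2, 1, [100.0]).values
    mu3 = fk.longtime_moment(m3, 1, [100.0]).values
    np.testing.assert_allclose(mu3, mu2, rtol=1e-10)


def test_simultaneous_reduces_to_elongator():
    F = 1e-3
    m2 = fk.build_two_state_elongator(6, 30, ref.formin(F))
    m4 = fk.build_simultaneous(
        6, 30, ref.formin(F), ref.capping_protein(0.0),
        ref.formin_primed(F), ref.capping_protein_primed(0.0),
    )
    pi2, pi4 = fk.stationary_distribution(m2), fk.stationary_distribution(m4)
    shared = [m4.index(lbl) for lbl in m2.labels]
    np.testing.assert_allclose(pi4[shared], pi2, atol=1e-10)
    np.testing.assert_allclose(
        fk.longtime_moment(m4, 1, [100.0]).values,
        fk.longtime_moment(m2, 1, [100.0]).values,
        rtol=1e-10,
    )


def test_custom_builder_errors():
    states = [fk.StateSpec("a", fk.POLYMERIZING, 1.0)]
    with pytest.raises(ModelValidationError):
        fk.build_custom(states, [("a", "nope", 1.0)])
    with pytest.raises(ModelValidationError):
        fk.build_custom(states * 2, [])
    with pytest.raises(ModelValidationError):
        fk.build_custom(
            states + [fk.StateSpec("b", fk.POLYMERIZING, 1.0)], [("a", "b", -1.0)]
        )


def test_disconnected_model_refuses_stationary_solve():
    states = [
        fk.StateSpec("a", fk.POLYMERIZING, 1.0),
        fk.StateSpec("b", fk.POLYMERIZING, 2.0),
    ]
    m = fk.build_custom(states, [])
    with pytest.raises(fk.ReducibleModelError):
        fk.stationary_distribution(m)


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(min_value=1, max_value=6), st.integers(min_value=0, max_value=2**31 - 1))
def test_random_custom_generator_column_sums(n, seed):
    """Random N-state models always satisfy the conservation structure."""
    rng = np.random.default_rng(seed)
    states = [
        fk.StateSpec(
            f"s{i}",
            fk.POLYMERIZING if rng.random() < 0.5 else fk.DEPOLYMERIZING,
            float(rng.uniform(0, 10)),
        )
        for i in range(n)
    ]
    transitions = [
        (f"s{j}", f"s{i}", float(rng.uniform(0, 5)))
        for i in range(n)
        for j in range(n)
        if i != j and rng.random() < 0.6
    ]
    m = fk.build_custom(states, transitions)
    assert np.max(np.abs(m.generator.sum(axis=0))) <= 1e-12 * max(
        1.0, np.abs(m.generator).max()
    )


def test_yaml_config_round_trip(simultaneous_model):
    text = simultaneous_model.to_yaml()
    back = fk.KineticModel.from_yaml(text)
    assert back.labels == simultaneous_model.labels
    np.testing.assert_allclose(back.generator, simultaneous_model.generator)
    assert [s.rate for s in back.states] == [s.rate for s in simultaneous_model.states]
    assert back.fingerprint() == simultaneous_model.fingerprint()


def test_json_config_round_trip(competitive_model):
    back = fk.KineticModel.from_json(competitive_model.to_json())
    np.testing.assert_allclose(back.generator, competitive_model.generator)
    assert back.labels == competitive_model.labels
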