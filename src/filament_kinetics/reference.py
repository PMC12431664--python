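"""Reference kinetic parameters for the canonical actin regulators.

Literature rates for formin mDia1 (an elongator that accelerates barbed-end
polymerization) and capping protein (a capper that halts it), plus the
"primed" constants governing binding to an already-occupied end in the
simultaneous-binding scheme.  All on-rate constants are in uM^-1 s^-1,
off-rates in s^-1, polymerization rates in subunits/s; 1 subunit of F-actin
adds SUBUNIT_LENGTH_UM micrometres of filament.
"""

from .model import RegulatorKinetics

SUBUNIT_LENGTH_UM = 0.0027
"""Filament length contributed by one actin subunit, in micrometres."""

BARE_RATE = 6.0
"""Polymerization rate of the bare barbed end, subunits/s."""

FORMIN_BOUND_RATE = 30.0
"""Polymerization rate of the formin-bound end, subunits/s."""

FORMIN_ON_RATE_CONSTANT = 29.1    # uM^-1 s^-1
FORMIN_OFF_RATE = 8.1e-5          # s^-1
CAPPER_ON_RATE_CONSTANT = 12.8    # uM^-1 s^-1
CAPPER_OFF_RATE = 2.0e-4          # s^-1

# binding to an already-occupied end (simultaneous-binding model)
FORMIN_ON_RATE_CONSTANT_PRIMED = 1.6    # formin binding a capped end
CAPPER_ON_RATE_CONSTANT_PRIMED = 0.21   # capper binding a formin-bound end
FORMIN_OFF_RATE_PRIMED = 6.2e-3
CAPPER_OFF_RATE_PRIMED = 6.2e-3

# two-state elongator parameters that best describe the mDia1 TIRF dataset
# (slower processive elongation than the textbook constants above)
TIRF_FORMIN_BOUND_RATE = 16.0
TIRF_FORMIN_ON_RATE_CONSTANT = 8.8
TIRF_FORMIN_OFF_RATE = 14.7e-5
TIRF_FORMIN_CONCENTRATION_UM = 5e-3   # 5 nM
TIRF_N_FILAMENTS = 37


def formin(concentration_uM: float) -> RegulatorKinetics:
    """Formin mDia1 kinetics at the given concentration (uM)."""
    return RegulatorKinetics(
        "formin", FORMIN_ON_RATE_CONSTANT, concentration_uM, FORMIN_OFF_RATE
    )


def capping_protein(concentration_uM: float) -> RegulatorKinetics:
    """Capping protein kinetics at the given concentration (uM)."""
    return RegulatorKinetics(
        "capping_protein", CAPPER_ON_RATE_CONSTANT, concentration_uM, CAPPER_OFF_RATE
    )


def formin_primed(concentration_uM: float) -> RegulatorKinetics:
    """Formin binding to a capped end (simultaneous-binding leg)."""
    return RegulatorKinetics(
        "formin'", FORMIN_ON_RATE_CONSTANT_PRIMED, concentration_uM,
        FORMIN_OFF_RATE_PRIMED,
    )


def capping_protein_primed(concentration_uM: float) -> RegulatorKinetics:
    """Capping protein binding to a formin-bound end (simultaneous-binding leg)."""
    return RegulatorKinetics(
        "capping_protein'", CAPPER_ON_RATE_CONSTANT_PRIMED, concentration_uM,
        CAPPER_OFF_RATE_PRIMED,
    )


def tirf_formin(concentration_uM: float = TIRF_FORMIN_CONCENTRATION_UM) -> RegulatorKinetics:
    """Formin kinetics used for the TIRF-experiment comparison."""
    return RegulatorKinetics(
        "formin_tirf", TIRF_FORMIN_ON_RATE_CONSTANT, concentration_uM,
        TIRF_FORMIN_OFF_RATE,
    )
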