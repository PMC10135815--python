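"""Internal unit system and reduced-unit conventions.

Internal units are the GROMACS-style set: length nm, time ps, energy
kJ/mol, mass amu (so that 1 kJ/mol = 1 amu nm^2 ps^-2 and no conversion
factors appear in the integrator).  Bead masses are expressed in the
bead-mass unit m0, mapped to 1 amu.

Observables are reported in the reduced units used throughout the study:
temperature in units of T0 = 100 K and time in units of tau = 1 ns, so a
simulation temperature of 2.0 means 200 K internally and a trajectory time
of 5000 tau means 5 us.
"""

KB = 0.0083145
"""Boltzmann constant, kJ mol^-1 K^-1."""

T0_KELVIN = 100.0
"""Reduced temperature unit T0 in kelvin."""

TAU_PS = 1000.0
"""Reduced time unit tau in picoseconds (1 ns)."""

NM_TO_ANGSTROM = 10.0


def kelvin(t_reduced: float) -> float:
    """Convert a temperature in T0 units to kelvin."""
    return t_reduced * T0_KELVIN


def kbt(t_reduced: float) -> float:
    """Thermal energy kB*T in kJ/mol for a temperature given in T0 units."""
    return KB * kelvin(t_reduced)


def tau_to_ps(t_tau: float) -> float:
    return t_tau * TAU_PS


def ps_to_tau(t_ps: float) -> float:
    return t_ps / TAU_PS
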