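"""Physical constants and the unit conventions used across the package.

Internal conventions:

* electrophysiology: mV, ms, pA (external interfaces), nA/uS/nF inside the
  cable solver (1 uS * 1 mV = 1 nA; 1 nF * 1 mV / 1 ms = 1 nA),
* geometry: um (morphologies), Angstrom (ion trajectories),
* lattice energies: units of k_B * T_REF with T_REF = 303.15 K.
"""

import numpy as np

#: elementary charge, C
E_CHARGE = 1.602176634e-19
#: Boltzmann constant, J/K
K_BOLTZMANN = 1.380649e-23
#: reference temperature for the lattice energy unit, K (30 degC)
T_REF_K = 303.15

#: energy of one elementary charge moved across 1 mV, in k_B*T_REF units.
#: Multiplying a gating charge (e0) by a membrane potential (mV) by this
#: factor yields an energy in the lattice Hamiltonian's native unit.
F_V = E_CHARGE * 1e-3 / (K_BOLTZMANN * T_REF_K)

#: pS * mV -> pA
PS_MV_TO_PA = 1e-3
#: uS * mV -> pA
US_MV_TO_PA = 1e3


def celsius_to_kelvin(t_c: float) -> float:
    t_k = t_c + 273.15
    if t_k <= 0:
        raise ValueError(f"temperature {t_c} degC is at or below absolute zero")
    return t_k


def beta_ref(t_c: float) -> float:
    """Inverse temperature for energies expressed in k_B*T_REF units."""
    return T_REF_K / celsius_to_kelvin(t_c)


def area_um2_to_cm2(a: float | np.ndarray):
    return a * 1e-8
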