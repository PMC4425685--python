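"""Unit conventions and physical constants used throughout the package.

Internal units are fixed package-wide:

========  =========
quantity  unit
========  =========
length    angstrom (A)
time      nanosecond (ns)
charge    elementary charge (e)
voltage   volt (V)
current   picoampere (pA)
conductance  nanosiemens (nS)
energy    electronvolt (eV)
========  =========

All conversions between these and external conventions live here so that no
module carries its own factors.
"""

# Boltzmann constant, eV / K
KB_EV = 8.617333262e-5

# elementary charge, coulomb
E_CHARGE_C = 1.602176634e-19

# 1 crossing of charge 1 e per ns = e / 1e-9 s = 1.602e-10 A = 160.218 pA
PA_PER_E_PER_NS = 160.2176634

# Coulomb prefactor e / (4 pi eps0 * 1 A), in volts.  phi = 14.3996 * q / r[A].
COULOMB_V_A = 14.399645478

# diffusion coefficients: 1e-5 cm^2/s  <->  A^2/ns
A2_PER_NS_PER_1E5_CM2_S = 100.0


def kT_eV(temperature_K: float) -> float:
    """Thermal energy k_B*T in eV."""
    return KB_EV * temperature_K


def d_cm2s_to_A2ns(d_1e5_cm2_s: float) -> float:
    """Convert a diffusion coefficient in 1e-5 cm^2/s to A^2/ns."""
    return d_1e5_cm2_s * A2_PER_NS_PER_1E5_CM2_S


def d_A2ns_to_cm2s(d_A2_ns: float) -> float:
    """Convert a diffusion coefficient in A^2/ns to 1e-5 cm^2/s."""
    return d_A2_ns / A2_PER_NS_PER_1E5_CM2_S
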