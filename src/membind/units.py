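"""Physical constants and shared unit conventions.

Internally all energies are kJ/mol, distances nm, angles degrees at the
public interfaces (radians only inside gradient code). Binding free
energies are reported in kcal/mol at the output boundary.
"""

import numpy as np

#: Boltzmann constant, kJ/mol/K
KB = 0.0083145

#: kJ per kcal
KCAL = 4.184

#: The simulation temperature ladder: 310-450 K in 10 K steps (15 values).
LADDER = tuple(range(310, 451, 10))


def kbt(temperature: float) -> float:
    """Thermal energy kB*T in kJ/mol at ``temperature`` (K)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0 K, got {temperature}")
    return KB * float(temperature)


def wrap_degrees(angle):
    """Wrap an angle (or array) into (-180, 180] degrees."""
    a = np.asarray(angle, dtype=float)
    wrapped = -(np.mod(-a + 180.0, 360.0) - 180.0)
    return wrapped if wrapped.ndim else float(wrapped)
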