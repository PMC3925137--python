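"""Physical constants and unit conversions.

All beam mechanics is done in SI internally; trajectory coordinates are
in angstrom and masses in dalton.  Every Da->kg / A->m conversion in the
package goes through this module.
"""

#: Boltzmann constant [J/K]
KB = 1.380649e-23

#: One dalton (unified atomic mass unit) [kg]
DALTON = 1.66053906660e-27

#: One angstrom [m]
ANGSTROM = 1e-10

#: One nanometre [m]
NANOMETRE = 1e-9

#: One picosecond [s]
PICOSECOND = 1e-12


def kbt(temperature: float) -> float:
    """Thermal energy k_B*T [J] at ``temperature`` [K]."""
    if temperature < 0:
        raise ValueError("temperature must be non-negative")
    return KB * temperature


def dalton_to_kg(mass_da: float) -> float:
    return mass_da * DALTON


def angstrom_to_m(x_a: float) -> float:
    return x_a * ANGSTROM
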