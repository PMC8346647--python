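"""Physical constants and unit conversions.

Internal convention throughout the package: energies in J mol⁻¹,
temperatures in Kelvin, heating rates in K s⁻¹.  Degrees Celsius and
kJ mol⁻¹ appear only at I/O boundaries (files, CLI, reports).
"""

from scipy.constants import R as GAS_CONSTANT  # 8.31446... J mol⁻¹ K⁻¹

#: Pre-exponential (frequency) factor fixed for every pseudo-component, s⁻¹.
DEFAULT_K0 = 1.67e13

#: Offset between the Celsius and Kelvin scales.
CELSIUS_OFFSET = 273.15


def c_to_k(t_celsius):
    """Convert °C to K (scalar or array)."""
    return t_celsius + CELSIUS_OFFSET


def k_to_c(t_kelvin):
    """Convert K to °C (scalar or array)."""
    return t_kelvin - CELSIUS_OFFSET


def beta_c_per_min_to_k_per_s(beta_c_per_min):
    """Convert a heating rate given in °C min⁻¹ to K s⁻¹."""
    return beta_c_per_min / 60.0


def kj_to_j(e_kj_per_mol):
    """Convert kJ mol⁻¹ to J mol⁻¹."""
    return e_kj_per_mol * 1e3


def j_to_kj(e_j_per_mol):
    """Convert J mol⁻¹ to kJ mol⁻¹."""
    return e_j_per_mol / 1e3
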