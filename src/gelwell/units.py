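"""Unit conversions between molar concentrations and absolute motif counts.

Internal model state is always an absolute count of Y-motifs in a droplet;
concentrations at the user-facing boundary are molar (mol/L). The two
conversions below are the only place the Avogadro constant and the
L <-> m^3 factor appear.
"""

AVOGADRO = 6.02214076e23  # 1/mol (exact, SI 2019)
BOLTZMANN = 1.380649e-23  # J/K (exact, SI 2019)

LITERS_PER_M3 = 1000.0


def motif_count(concentration_molar: float, volume_m3: float) -> float:
    """Absolute number of motifs at molar concentration *c* in volume *V* (m^3)."""
    if concentration_molar < 0:
        raise ValueError(f"concentration must be >= 0, got {concentration_molar}")
    if volume_m3 < 0:
        raise ValueError(f"volume must be >= 0, got {volume_m3}")
    return concentration_molar * LITERS_PER_M3 * volume_m3 * AVOGADRO


def molar_concentration(count: float, volume_m3: float) -> float:
    """Molar concentration (mol/L) of *count* motifs in volume *V* (m^3)."""
    if volume_m3 <= 0:
        raise ValueError(f"volume must be > 0, got {volume_m3}")
    return count / (AVOGADRO * LITERS_PER_M3 * volume_m3)


def number_density(concentration_molar: float) -> float:
    """Convert mol/L to count/m^3."""
    return concentration_molar * LITERS_PER_M3 * AVOGADRO
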