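"""Physical constants in the GROMACS-consistent unit system (nm, ps, amu, kJ/mol, e, K, D)."""

#: Boltzmann constant, kJ mol^-1 K^-1
KB = 0.0083144621

#: Coulomb prefactor 1/(4 pi eps0), kJ mol^-1 nm e^-2
COULOMB = 138.935485

#: Dipole-moment conversion: 1 e nm in Debye
E_NM_TO_DEBYE = 48.0321

#: Volume per molecule at a 1 M standard concentration, nm^3
STANDARD_VOLUME_1M = 1.66054

#: Default simulation temperature, K
DEFAULT_TEMPERATURE = 300.0


def beta(temperature: float) -> float:
    """Inverse thermal energy 1/(k_B T) in mol kJ^-1."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return 1.0 / (KB * temperature)
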