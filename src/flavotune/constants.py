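"""Physical constants and unit bridges.

All Coulomb prefactors are derived from a single CODATA-based value so that
the ESTM (eV) and potential-map (kT/e) routes through the same bilinear form
agree to machine precision.
"""

#: Coulomb constant, eV·Å·e⁻² (e²/(4πε₀) in eV·Å).
K_COULOMB_EV = 14.399645

#: 1 eV in kcal/mol.
EV_TO_KCAL = 23.060548

#: Coulomb constant, kcal·Å·mol⁻¹·e⁻² (≈ 332.064).
K_COULOMB_KCAL = K_COULOMB_EV * EV_TO_KCAL

#: Gas constant, kcal·mol⁻¹·K⁻¹.
R_KCAL = 1.987204259e-3

#: Default temperature, K (standard conditions for potential maps).
T_DEFAULT = 298.15


def kt_kcal(temperature: float = T_DEFAULT) -> float:
    """Thermal energy RT in kcal/mol."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return R_KCAL * temperature


def kt_ev(temperature: float = T_DEFAULT) -> float:
    """Thermal energy kT in eV (≈ 0.025693 eV at 298.15 K)."""
    return kt_kcal(temperature) / EV_TO_KCAL
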