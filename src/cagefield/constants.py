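"""Physical constants and unit conversions.

All positions are in Å, charges in units of the elementary charge e,
electric fields in V Å⁻¹, dipole moments in Debye and energies in
kcal mol⁻¹.  Two conversion factors that agree only to three significant
figures are kept as distinct named constants on purpose: conflating them
is a classic source of ~0.04% unit bugs in field–dipole energy code.
"""

#: Coulomb constant k_C in V·Å·e⁻¹: the field of a unit point charge at
#: 1 Å is 14.3996 V Å⁻¹ (e/(4πε₀) expressed in V·Å).
COULOMB_K = 14.3996

#: Debye per e·Å (k_D): a +e/−e pair separated by 1 Å has |μ| = 4.80320 D.
DEBYE_PER_E_ANGSTROM = 4.80320

#: Field–dipole energy factor k_E in kcal·mol⁻¹·D⁻¹·(V Å⁻¹)⁻¹:
#: ΔE = k_E · F · μ for F in V Å⁻¹ and μ in Debye.
FIELD_DIPOLE_K = 4.8009

#: Molar gas constant in kcal·mol⁻¹·K⁻¹.
R_GAS_KCAL = 1.98720425e-3
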