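# Compound registry: elemental formula (C/H/O/N counts), molar mass (g/mol)
# and, for weak acids, the acid dissociation constant as pKa.
#
# pKa sources: caproic (hexanoic) acid 4.88, consistent with CRC Handbook
# values (4.85-4.88) and with the speciation arithmetic this package
# reproduces; acetic 4.76, butyric 4.82, lactic 3.86 (CRC Handbook, 25 C).
# Molar masses are computed from the formulas with IUPAC 2021 atomic weights.
# "biomass" is the standard ash-free cell composition CH1.8O0.5N0.2
# (24.6 g per C-mol); it has no pKa and enters only electron balances.
caproate:
  aliases: [caproic_acid, hexanoate, hexanoic_acid, CA]
  formula: {C: 6, H: 12, O: 2}
  molar_mass: 116.16
  pKa: 4.88
butyrate:
  aliases: [butyric_acid]
  formula: {C: 4, H: 8, O: 2}
  molar_mass: 88.11
  pKa: 4.82
acetate:
  aliases: [acetic_acid]
  formula: {C: 2, H: 4, O: 2}
  molar_mass: 60.05
  pKa: 4.76
lactate:
  aliases: [lactic_acid]
  formula: {C: 3, H: 6, O: 3}
  molar_mass: 90.08
  pKa: 3.86
glucose:
  formula: {C: 6, H: 12, O: 6}
  molar_mass: 180.16
ethanol:
  formula: {C: 2, H: 6, O: 1}
  molar_mass: 46.07
hydrogen:
  aliases: [H2]
  formula: {H: 2}
  molar_mass: 2.016
carbon_dioxide:
  aliases: [CO2]
  formula: {C: 1, O: 2}
  molar_mass: 44.01
water:
  aliases: [H2O]
  formula: {H: 2, O: 1}
  molar_mass: 18.02
biomass:
  formula: {C: 1.0, H: 1.8, O: 0.5, N: 0.2}
  molar_mass: 24.63
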