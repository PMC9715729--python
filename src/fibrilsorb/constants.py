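"""Physical constants and unit conversions used throughout the package.

All geometry is in nanometres, times in picoseconds, masses in grams
unless a function says otherwise.
"""

#: Avogadro constant, 1/mol.
N_AVOGADRO = 6.022e23

#: Molar mass of the anhydroglucose repeat unit (C6H10O5), g/mol.
M_ANHYDROGLUCOSE = 162.14

#: Molar mass of water, g/mol.  Also the per-chain terminal-group mass
#: correction for a condensation polymer (one H and one OH chain end).
M_WATER = 18.02

#: Gas constant, J/(mol K).
R_GAS = 8.314

#: Specific gas constant of water vapour, J/(kg K).
R_VAPOUR = 461.5

#: Conversion factor: diffusion coefficient in nm^2/ps expressed in units
#: of 1e-5 cm^2/s.  1 nm^2/ps = 1e-14 cm^2 / 1e-12 s = 1e-2 cm^2/s.
NM2_PS_TO_1E5_CM2_S = 1.0e3

#: Celsius -> Kelvin offset.
KELVIN_OFFSET = 273.15
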