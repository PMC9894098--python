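"""Physical constants and cell geometry shared by all model components.

Units follow the conventions of the source human ventricular model:
voltages in mV, time in ms, concentrations in mM, per-capacitance current
densities in uA/uF (== pA/pF), absolute currents in pA, conductances in
nS (absolute) or mS/uF (density), capacitances in pF.
"""

# Thermodynamics
R_GAS = 8314.0        # J / (kmol K)
TEMPERATURE = 310.0   # K
FARADAY = 96485.0     # C / mol

RTF = R_GAS * TEMPERATURE / FARADAY  # ~26.71 mV

# Extracellular milieu (mM)
NA_O = 140.0
CA_O = 1.8
K_O = 5.4

# Ventricular cell geometry (cm); cylinder approximation
CELL_LENGTH = 0.01
CELL_RADIUS = 0.0011

V_CELL = 1000.0 * 3.14 * CELL_RADIUS * CELL_RADIUS * CELL_LENGTH  # uL
A_GEO = 2.0 * 3.14 * CELL_RADIUS * CELL_RADIUS + 2.0 * 3.14 * CELL_RADIUS * CELL_LENGTH
A_CAP = 2.0 * A_GEO          # cm^2 (membrane folding factor 2)
V_MYO = 0.68 * V_CELL
V_NSR = 0.0552 * V_CELL
V_JSR = 0.0048 * V_CELL
V_SS = 0.02 * V_CELL

# Membrane capacitance at 1 uF/cm^2
CM_CAPACITANCE_PF = A_CAP * 1.0e6  # pF (~153.4 pF)

# Fibroblast (active membrane model)
FIB_CAPACITANCE_PF = 6.3

# Custom therapeutic cell
CUSTOM_CAPACITANCE_PF = 40.0
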