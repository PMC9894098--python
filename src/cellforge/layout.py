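"""Flat state-vector and current-vector layouts for the coupled system.

The integrator operates on one fixed-length float64 vector holding the
cardiomyocyte block, the (lumped) fibroblast block and the (lumped) custom
cell block.  Unused blocks are simply inert.  Keeping the layout static lets
a single compiled kernel serve every experiment.
"""

# ---------------------------------------------------------------- CM block
IV = 0
INAI, INASS, IKI, IKSS = 1, 2, 3, 4
ICAI, ICASS, ICANSR, ICAJSR = 5, 6, 7, 8
IM, IH, IJ = 9, 10, 11                 # fast Na+ gates (ten Tusscher kinetics)
IML, IHL, IHLP = 12, 13, 14            # late Na+
IA, IIF, IIS, IAP, IIFP, IISP = 15, 16, 17, 18, 19, 20   # transient outward
ID, IFF, IFS, IFCAF, IFCAS, IJCA, INCA, IFFP, IFCAFP = 21, 22, 23, 24, 25, 26, 27, 28, 29
IXRF, IXRS = 30, 31
IXS1, IXS2 = 32, 33
IXK1 = 34
IJRELNP, IJRELP = 35, 36
ICAMKT = 37
N_CM = 38

# ----------------------------------------------------------- fibroblast block
FIB_V = 38
FIB_R = 39
FIB_S = 40
N_FIB_STATES = 3

# ---------------------------------------------------------- custom-cell block
CU0 = 41
CU_V = CU0 + 0
# hCM channel gates
CU_M, CU_H, CU_J = CU0 + 1, CU0 + 2, CU0 + 3
CU_ML, CU_HL = CU0 + 4, CU0 + 5
CU_A, CU_IF, CU_IS = CU0 + 6, CU0 + 7, CU0 + 8
CU_D, CU_FF, CU_FS, CU_FCAF, CU_FCAS, CU_JCA, CU_NCA = (
    CU0 + 9, CU0 + 10, CU0 + 11, CU0 + 12, CU0 + 13, CU0 + 14, CU0 + 15)
CU_XRF, CU_XRS = CU0 + 16, CU0 + 17
CU_XS1, CU_XS2 = CU0 + 18, CU0 + 19
CU_XK1 = CU0 + 20
# hCIC channel gates
CU_CNA_M, CU_CNA_H = CU0 + 21, CU0 + 22
CU_CBK_X = CU0 + 23
CU_CTO_A, CU_CTO_I = CU0 + 24, CU0 + 25
# hMSC channel gates
CU_MTO_A, CU_MTO_I = CU0 + 26, CU0 + 27
CU_MNA_M, CU_MNA_H = CU0 + 28, CU0 + 29
CU_MCAL_D, CU_MCAL_F = CU0 + 30, CU0 + 31
CU_MKCA_X = CU0 + 32
CU_MDR_X = CU0 + 33
# CF channel gates
CU_R, CU_S = CU0 + 34, CU0 + 35
N_CU_STATES = 36

N_Y = CU0 + N_CU_STATES  # 77

# ------------------------------------------------------------ current vector
# Cardiomyocyte membrane currents in uA/uF; SR fluxes in mM/ms; gap currents
# in pA; custom-cell channel currents in pA.
C_INA, C_INAL, C_ITO, C_ICAL, C_ICANA, C_ICAK = 0, 1, 2, 3, 4, 5
C_IKR, C_IKS, C_IK1, C_INACA_I, C_INACA_SS, C_INAK = 6, 7, 8, 9, 10, 11
C_INAB, C_ICAB, C_IKB, C_IPCA = 12, 13, 14, 15
C_JREL, C_JUP = 16, 17
C_ISTIM = 18
C_IGAP_FIB = 19      # total pA leaving the CM through fibroblast junctions
C_IGAP_CU = 20       # total pA leaving the CM through custom-cell junctions
C_FIB_IKV, C_FIB_IKIR, C_FIB_INAK, C_FIB_IBNA = 21, 22, 23, 24
C_CU_FIRST = 25      # 21 per-channel custom-cell currents, pA
C_IGAP_CU_ONE = 46   # pA entering one custom cell through its junction
N_CUR = 47

# ------------------------------------------------------- custom channel enum
(
    HCM_NA, HCM_NAL, HCM_TO, HCM_CAL, HCM_KR, HCM_KS, HCM_K1,
    HCIC_NA, HCIC_KIR, HCIC_BK, HCIC_TO,
    HMSC_TO, HMSC_TO_SS, HMSC_NA, HMSC_CAL, HMSC_KCA, HMSC_DR,
    CF_KV, CF_KIR, CF_NAK,
    PASSIVE_LEAK,
) = range(21)
N_CHANNELS = 21

CHANNEL_NAMES = [
    "hcm_na", "hcm_nal", "hcm_to", "hcm_cal", "hcm_kr", "hcm_ks", "hcm_k1",
    "hcic_na", "hcic_kir", "hcic_bk", "hcic_to",
    "hmsc_to", "hmsc_to_ss", "hmsc_na", "hmsc_cal", "hmsc_kca", "hmsc_dr",
    "cf_kv", "cf_kir", "cf_nak",
    "passive_leak",
]

CURRENT_NAMES = [
    "INa", "INaL", "Ito", "ICaL", "ICaNa", "ICaK",
    "IKr", "IKs", "IK1", "INaCa_i", "INaCa_ss", "INaK",
    "INab", "ICab", "IKb", "IpCa",
    "Jrel", "Jup",
    "Istim", "Igap_fib", "Igap_custom",
    "fib_IKv", "fib_IKir", "fib_INaK", "fib_IbNa",
] + [f"cu_{n}" for n in CHANNEL_NAMES] + ["Igap_custom_one"]
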