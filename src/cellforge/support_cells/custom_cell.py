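"""The composable custom therapeutic cell.

A custom cell is an isopotential 40 pF membrane carrying an arbitrary roster
of channels from the library, each with a non-negative scaling factor on its
baseline maximal conductance.  Intracellular ion concentrations are fixed
(never integrated); gating variables are integrated normally.  Total ionic
current is the scaled sum over the roster.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .. import layout as L
from ..constants import CUSTOM_CAPACITANCE_PF, K_O, NA_O, RTF
from ..cardiomyocyte.ord import (
    ical_fluxes, ical_rates, ik1_rates, ikr_rates, iks_rates,
    na_fast_rates, na_late_rates, ito_rates,
)
from .channels import (
    CHANNEL_LIBRARY, hcic_bk_rates, hcic_to_rates, hmsc_cal_rates,
    hmsc_dr_rates, hmsc_kca_rates, hmsc_to_rates,
)
from .fibroblast import fib_kir_density, fib_kv_rates, fib_nak_density

# Fixed intracellular concentration set shared by every custom cell (mM);
# the resting milieu of the ventricular source model, applied to all Nernst
# and flux calculations regardless of a channel's cell type of origin.
CUSTOM_NAI = 7.23
CUSTOM_KI = 143.79
CUSTOM_CAI = 8.54e-5

# Apparent L-type reversal used by the ohmic hMSC Ca2+ component (mV)
HMSC_ECA_APP = 60.0


@dataclass(frozen=True)
class CustomCellSpec:
    """Roster of channel names with per-channel scaling factors."""

    roster: tuple[str, ...]
    scalings: tuple[float, ...] = ()
    capacitance: float = CUSTOM_CAPACITANCE_PF
    concentrations: tuple[float, float, float] = (CUSTOM_NAI, CUSTOM_KI, CUSTOM_CAI)

    def __post_init__(self):
        if self.capacitance != CUSTOM_CAPACITANCE_PF:
            raise ValueError("custom cell capacitance is fixed at 40 pF")
        if len(set(self.roster)) != len(self.roster):
            raise ValueError("duplicate channel in roster")
        for name in self.roster:
            if name not in CHANNEL_LIBRARY:
                raise ValueError(f"unknown channel identity {name!r}")
        scal = self.scalings if self.scalings else tuple(1.0 for _ in self.roster)
        if len(scal) != len(self.roster):
            raise ValueError("one scaling factor per roster channel required")
        for s in scal:
            if not (s >= 0.0):
                raise ValueError(f"scaling factors must be >= 0, got {s}")
        object.__setattr__(self, "scalings", scal)

    def with_scalings(self, scalings) -> "CustomCellSpec":
        return CustomCellSpec(roster=self.roster, scalings=tuple(float(s) for s in scalings))

    def density_vector(self) -> np.ndarray:
        """Effective conductance density per library channel (baseline x
        scaling; zero for channels not on the roster)."""
        dens = np.zeros(L.N_CHANNELS)
        for name, s in zip(self.roster, self.scalings):
            ch = CHANNEL_LIBRARY[name]
            dens[ch.index] = ch.baseline * s
        return dens


@njit(cache=True)
def cu_block(y, dy, ginf, gtau, cur, dens, i_gap_pa):
    """Custom-cell derivatives.  ``dens`` holds effective conductance
    densities per library channel; ``i_gap_pa`` is the gap current (pA)
    leaving the custom cell toward the cardiomyocyte.  Channels with zero
    density are skipped entirely (their gates stay frozen)."""
    v = y[L.CU_V]
    ena = RTF * math.log(NA_O / CUSTOM_NAI)
    ek = RTF * math.log(K_O / CUSTOM_KI)
    eks = RTF * math.log((K_O + 0.01833 * NA_O) / (CUSTOM_KI + 0.01833 * CUSTOM_NAI))

    itot = 0.0  # pA/pF

    # ---- hCM channels (ventricular formulations, CaMK-naive branch only)
    if dens[L.HCM_NA] > 0.0:
        minf, taum, hinf, tauh, jinf, tauj = na_fast_rates(v)
        ginf[L.CU_M] = minf
        gtau[L.CU_M] = taum
        ginf[L.CU_H] = hinf
        gtau[L.CU_H] = tauh
        ginf[L.CU_J] = jinf
        gtau[L.CU_J] = tauj
        i = dens[L.HCM_NA] * y[L.CU_M] ** 3 * y[L.CU_H] * y[L.CU_J] * (v - ena)
        cur[L.C_CU_FIRST + L.HCM_NA] = i
        itot += i
    if dens[L.HCM_NAL] > 0.0:
        mlinf, tml, hlinf, thl, _, _ = na_late_rates(v)
        ginf[L.CU_ML] = mlinf
        gtau[L.CU_ML] = tml
        ginf[L.CU_HL] = hlinf
        gtau[L.CU_HL] = thl
        i = dens[L.HCM_NAL] * y[L.CU_ML] * y[L.CU_HL] * (v - ena)
        cur[L.C_CU_FIRST + L.HCM_NAL] = i
        itot += i
    if dens[L.HCM_TO] > 0.0:
        ainf, ta, iinf, tif, tis, aif, _, _, _ = ito_rates(v)
        ginf[L.CU_A] = ainf
        gtau[L.CU_A] = ta
        ginf[L.CU_IF] = iinf
        gtau[L.CU_IF] = tif
        ginf[L.CU_IS] = iinf
        gtau[L.CU_IS] = tis
        igate = aif * y[L.CU_IF] + (1.0 - aif) * y[L.CU_IS]
        i = dens[L.HCM_TO] * y[L.CU_A] * igate * (v - ek)
        cur[L.C_CU_FIRST + L.HCM_TO] = i
        itot += i
    if dens[L.HCM_CAL] > 0.0:
        (dinf, td, finf, tff, tfs, tfcaf, tfcas, afcaf, tjca, _, _) = ical_rates(v)
        ginf[L.CU_D] = dinf
        gtau[L.CU_D] = td
        ginf[L.CU_FF] = finf
        gtau[L.CU_FF] = tff
        ginf[L.CU_FS] = finf
        gtau[L.CU_FS] = tfs
        ginf[L.CU_FCAF] = finf
        gtau[L.CU_FCAF] = tfcaf
        ginf[L.CU_FCAS] = finf
        gtau[L.CU_FCAS] = tfcas
        ginf[L.CU_JCA] = finf
        gtau[L.CU_JCA] = tjca
        km2n = y[L.CU_JCA] * 1.0
        anca = 1.0 / (1000.0 / km2n + (1.0 + 0.002 / CUSTOM_CAI) ** 4)
        ginf[L.CU_NCA] = anca * 1000.0 / km2n
        gtau[L.CU_NCA] = 1.0 / km2n
        phi_ca, phi_na, phi_k = ical_fluxes(v, CUSTOM_CAI, CUSTOM_NAI, CUSTOM_KI)
        f = 0.6 * y[L.CU_FF] + 0.4 * y[L.CU_FS]
        fca = afcaf * y[L.CU_FCAF] + (1.0 - afcaf) * y[L.CU_FCAS]
        nca = y[L.CU_NCA]
        gate = y[L.CU_D] * (f * (1.0 - nca) + y[L.CU_JCA] * fca * nca)
        pca = dens[L.HCM_CAL]
        i = (pca * phi_ca + 0.00125 * pca * phi_na + 3.574e-4 * pca * phi_k) * gate
        cur[L.C_CU_FIRST + L.HCM_CAL] = i
        itot += i
    if dens[L.HCM_KR] > 0.0:
        xrinf, txrf, txrs, axrf, rkr = ikr_rates(v)
        ginf[L.CU_XRF] = xrinf
        gtau[L.CU_XRF] = txrf
        ginf[L.CU_XRS] = xrinf
        gtau[L.CU_XRS] = txrs
        xr = axrf * y[L.CU_XRF] + (1.0 - axrf) * y[L.CU_XRS]
        i = dens[L.HCM_KR] * math.sqrt(K_O / 5.4) * xr * rkr * (v - ek)
        cur[L.C_CU_FIRST + L.HCM_KR] = i
        itot += i
    if dens[L.HCM_KS] > 0.0:
        xs1inf, txs1, txs2 = iks_rates(v)
        ginf[L.CU_XS1] = xs1inf
        gtau[L.CU_XS1] = txs1
        ginf[L.CU_XS2] = xs1inf
        gtau[L.CU_XS2] = txs2
        ksca = 1.0 + 0.6 / (1.0 + (3.8e-5 / CUSTOM_CAI) ** 1.4)
        i = dens[L.HCM_KS] * ksca * y[L.CU_XS1] * y[L.CU_XS2] * (v - eks)
        cur[L.C_CU_FIRST + L.HCM_KS] = i
        itot += i
    if dens[L.HCM_K1] > 0.0:
        xk1inf, txk1, rk1 = ik1_rates(v, K_O)
        ginf[L.CU_XK1] = xk1inf
        gtau[L.CU_XK1] = txk1
        i = dens[L.HCM_K1] * math.sqrt(K_O) * rk1 * y[L.CU_XK1] * (v - ek)
        cur[L.C_CU_FIRST + L.HCM_K1] = i
        itot += i

    # ---- hCIC channels
    if dens[L.HCIC_NA] > 0.0:
        minf, taum, hinf, tauh, _, _ = na_fast_rates(v)
        ginf[L.CU_CNA_M] = minf
        gtau[L.CU_CNA_M] = taum
        ginf[L.CU_CNA_H] = hinf
        gtau[L.CU_CNA_H] = tauh
        i = dens[L.HCIC_NA] * y[L.CU_CNA_M] ** 3 * y[L.CU_CNA_H] * (v - ena)
        cur[L.C_CU_FIRST + L.HCIC_NA] = i
        itot += i
    if dens[L.HCIC_KIR] > 0.0:
        ek_local = ek
        i = fib_kir_density(v, ek_local, dens[L.HCIC_KIR])
        cur[L.C_CU_FIRST + L.HCIC_KIR] = i
        itot += i
    if dens[L.HCIC_BK] > 0.0:
        xinf, taux = hcic_bk_rates(v)
        ginf[L.CU_CBK_X] = xinf
        gtau[L.CU_CBK_X] = taux
        i = dens[L.HCIC_BK] * y[L.CU_CBK_X] * (v - ek)
        cur[L.C_CU_FIRST + L.HCIC_BK] = i
        itot += i
    if dens[L.HCIC_TO] > 0.0:
        ainf, taua, iinf, taui = hcic_to_rates(v)
        ginf[L.CU_CTO_A] = ainf
        gtau[L.CU_CTO_A] = taua
        ginf[L.CU_CTO_I] = iinf
        gtau[L.CU_CTO_I] = taui
        i = dens[L.HCIC_TO] * y[L.CU_CTO_A] * y[L.CU_CTO_I] * (v - ek)
        cur[L.C_CU_FIRST + L.HCIC_TO] = i
        itot += i

    # ---- hMSC channels
    if dens[L.HMSC_TO] > 0.0:
        ainf, taua, iinf, taui = hmsc_to_rates(v)
        ginf[L.CU_MTO_A] = ainf
        gtau[L.CU_MTO_A] = taua
        ginf[L.CU_MTO_I] = iinf
        gtau[L.CU_MTO_I] = taui
        i = dens[L.HMSC_TO] * y[L.CU_MTO_A] * y[L.CU_MTO_I] * (v - ek)
        cur[L.C_CU_FIRST + L.HMSC_TO] = i
        itot += i
    if dens[L.HMSC_TO_SS] > 0.0:
        ainf, _, _, _ = hmsc_to_rates(v)
        i = dens[L.HMSC_TO_SS] * ainf * (v - ek)
        cur[L.C_CU_FIRST + L.HMSC_TO_SS] = i
        itot += i
    if dens[L.HMSC_NA] > 0.0:
        minf, taum, hinf, tauh, _, _ = na_fast_rates(v)
        ginf[L.CU_MNA_M] = minf
        gtau[L.CU_MNA_M] = taum
        ginf[L.CU_MNA_H] = hinf
        gtau[L.CU_MNA_H] = tauh
        i = dens[L.HMSC_NA] * y[L.CU_MNA_M] ** 3 * y[L.CU_MNA_H] * (v - ena)
        cur[L.C_CU_FIRST + L.HMSC_NA] = i
        itot += i
    if dens[L.HMSC_CAL] > 0.0:
        dinf, taud, finf, tauf = hmsc_cal_rates(v)
        ginf[L.CU_MCAL_D] = dinf
        gtau[L.CU_MCAL_D] = taud
        ginf[L.CU_MCAL_F] = finf
        gtau[L.CU_MCAL_F] = tauf
        i = dens[L.HMSC_CAL] * y[L.CU_MCAL_D] * y[L.CU_MCAL_F] * (v - HMSC_ECA_APP)
        cur[L.C_CU_FIRST + L.HMSC_CAL] = i
        itot += i
    if dens[L.HMSC_KCA] > 0.0:
        xinf, taux = hmsc_kca_rates(v)
        ginf[L.CU_MKCA_X] = xinf
        gtau[L.CU_MKCA_X] = taux
        i = dens[L.HMSC_KCA] * y[L.CU_MKCA_X] * (v - ek)
        cur[L.C_CU_FIRST + L.HMSC_KCA] = i
        itot += i
    if dens[L.HMSC_DR] > 0.0:
        xinf, taux = hmsc_dr_rates(v)
        ginf[L.CU_MDR_X] = xinf
        gtau[L.CU_MDR_X] = taux
        i = dens[L.HMSC_DR] * y[L.CU_MDR_X] ** 2 * (v - ek)
        cur[L.C_CU_FIRST + L.HMSC_DR] = i
        itot += i

    # ---- CF channels
    if dens[L.CF_KV] > 0.0:
        rinf, taur, sinf, taus = fib_kv_rates(v)
        ginf[L.CU_R] = rinf
        gtau[L.CU_R] = taur
        ginf[L.CU_S] = sinf
        gtau[L.CU_S] = taus
        i = dens[L.CF_KV] * y[L.CU_R] * y[L.CU_S] * (v - ek)
        cur[L.C_CU_FIRST + L.CF_KV] = i
        itot += i
    if dens[L.CF_KIR] > 0.0:
        i = fib_kir_density(v, ek, dens[L.CF_KIR])
        cur[L.C_CU_FIRST + L.CF_KIR] = i
        itot += i
    if dens[L.CF_NAK] > 0.0:
        i = fib_nak_density(v, CUSTOM_NAI, dens[L.CF_NAK] / 2.002)
        cur[L.C_CU_FIRST + L.CF_NAK] = i
        itot += i

    # ---- passive ohmic leak (pure-resistor cell variant)
    if dens[L.PASSIVE_LEAK] > 0.0:
        i = dens[L.PASSIVE_LEAK] * (v - 0.0)
        cur[L.C_CU_FIRST + L.PASSIVE_LEAK] = i
        itot += i

    # densities (pA/pF) -> absolute currents (pA)
    for k in range(L.N_CHANNELS):
        cur[L.C_CU_FIRST + k] *= CUSTOM_CAPACITANCE_PF

    dy[L.CU_V] = -(itot + i_gap_pa / CUSTOM_CAPACITANCE_PF)


def cu_initial_state() -> np.ndarray:
    """Custom-cell block initial values: resting potential near the
    ventricular resting potential with gates at generic resting values."""
    y = np.zeros(L.N_CU_STATES)
    y[0] = -60.0
    # inactivation-type gates start available
    for i in (L.CU_H, L.CU_J, L.CU_HL, L.CU_IF, L.CU_IS, L.CU_FF, L.CU_FS,
              L.CU_FCAF, L.CU_FCAS, L.CU_JCA, L.CU_CNA_H, L.CU_CTO_I,
              L.CU_MTO_I, L.CU_MNA_H, L.CU_MCAL_F, L.CU_S):
        y[i - L.CU0] = 1.0
    y[L.CU_XK1 - L.CU0] = 0.99
    return y


def custom_cell_rhs(state: np.ndarray, spec: CustomCellSpec, i_gap_pa: float = 0.0):
    """Stand-alone custom-cell right-hand side.

    ``state`` is the 36-entry custom block (Vm followed by the gate layout);
    returns (dstate, currents) with per-channel currents in pA.
    """
    if state.shape[0] != L.N_CU_STATES:
        raise ValueError(f"custom cell state has {L.N_CU_STATES} entries")
    if not np.all(np.isfinite(state)):
        bad = int(np.where(~np.isfinite(state))[0][0])
        raise ValueError(f"non-finite custom cell state entry at index {bad}")
    y = np.zeros(L.N_Y)
    y[L.CU0:] = state
    dy = np.zeros(L.N_Y)
    ginf = np.zeros(L.N_Y)
    gtau = np.full(L.N_Y, -1.0)
    cur = np.zeros(L.N_CUR)
    cu_block(y, dy, ginf, gtau, cur, spec.density_vector(), i_gap_pa)
    dstate = np.zeros(L.N_CU_STATES)
    dstate[0] = dy[L.CU_V]
    for i in range(L.CU0 + 1, L.N_Y):
        if gtau[i] > 0.0:
            dstate[i - L.CU0] = (ginf[i] - y[i]) / gtau[i]
    currents = {name: cur[L.C_CU_FIRST + k] for k, name in enumerate(L.CHANNEL_NAMES)}
    return dstate, currents
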