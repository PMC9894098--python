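"""Active ventricular fibroblast membrane model (four-current formulation:
time- and voltage-dependent K+, inward rectifier K+, Na+/K+ pump and
background Na+), used both for the fibrotic coupling condition and as the
source of the CF channel family available to custom cells.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .. import layout as L
from ..constants import FIB_CAPACITANCE_PF, K_O, NA_O, RTF

# Fixed fibroblast intracellular milieu (mM)
FIB_NAI = 8.5528
FIB_KI = 129.4349

G_KV = 0.25        # nS/pF
G_KIR = 0.4822     # nS/pF
I_NAK_MAX = 2.002  # pA/pF
G_B_NA = 0.0095    # nS/pF
KM_K = 1.0
KM_NA = 11.0
V_REV = -150.0
B_FACTOR = -200.0


@njit(cache=True)
def fib_kv_rates(v):
    rinf = 1.0 / (1.0 + math.exp(-(v + 20.0) / 11.0))
    taur = 20.3 + 138.0 * math.exp(-(((v + 20.0) / 25.9) ** 2))
    sinf = 1.0 / (1.0 + math.exp((v + 23.0) / 7.0))
    taus = 1574.0 + 5268.0 * math.exp(-(((v + 23.0) / 22.7) ** 2))
    return rinf, taur, sinf, taus


@njit(cache=True)
def fib_kir_density(v, ek, g_kir):
    """Inward rectifier with voltage-shifted alpha/beta open fraction."""
    dv = v - ek
    a = 0.1 / (1.0 + math.exp(0.06 * (dv - 200.0)))
    b = ((3.0 * math.exp(0.0002 * (dv + 100.0)) + math.exp(0.1 * (dv - 10.0)))
         / (1.0 + math.exp(-0.5 * dv)))
    return g_kir * (a / (a + b)) * dv


@njit(cache=True)
def fib_nak_density(v, nai, scale):
    return (scale * I_NAK_MAX * (K_O / (K_O + KM_K))
            * (nai ** 1.5 / (nai ** 1.5 + KM_NA ** 1.5))
            * (v - V_REV) / (v - B_FACTOR))


@njit(cache=True)
def fib_block(y, dy, ginf, gtau, cur, i_gap_pa):
    """Fibroblast derivatives; ``i_gap_pa`` is the gap current (pA) leaving
    the fibroblast toward the cardiomyocyte."""
    v = y[L.FIB_V]
    ek = RTF * math.log(K_O / FIB_KI)
    ena = RTF * math.log(NA_O / FIB_NAI)

    rinf, taur, sinf, taus = fib_kv_rates(v)
    ginf[L.FIB_R] = rinf
    gtau[L.FIB_R] = taur
    ginf[L.FIB_S] = sinf
    gtau[L.FIB_S] = taus

    ikv = G_KV * y[L.FIB_R] * y[L.FIB_S] * (v - ek)
    ikir = fib_kir_density(v, ek, G_KIR)
    inak = fib_nak_density(v, FIB_NAI, 1.0)
    ibna = G_B_NA * (v - ena)

    itot = ikv + ikir + inak + ibna  # pA/pF
    dy[L.FIB_V] = -(itot + i_gap_pa / FIB_CAPACITANCE_PF)

    cur[L.C_FIB_IKV] = ikv
    cur[L.C_FIB_IKIR] = ikir
    cur[L.C_FIB_INAK] = inak
    cur[L.C_FIB_IBNA] = ibna


def fib_initial_state() -> np.ndarray:
    """Resting fibroblast: Vm near its own resting potential."""
    return np.array([-49.6, 0.0, 1.0])


def fibroblast_rhs(state: np.ndarray, i_external_pa: float = 0.0):
    """Stand-alone fibroblast right-hand side.

    Parameters
    ----------
    state : array (v, r, s)
    i_external_pa : external (gap) current in pA, positive outward.

    Returns
    -------
    (dstate, currents) with currents as a dict of pA/pF densities.
    """
    if state.shape[0] != 3:
        raise ValueError("fibroblast state is (v, r, s)")
    names = ("v", "r", "s")
    for n, val in zip(names, state):
        if not np.isfinite(val):
            raise ValueError(f"non-finite fibroblast state entry {n!r} = {val}")
    y = np.zeros(L.N_Y)
    y[L.FIB_V:L.FIB_S + 1] = state
    dy = np.zeros(L.N_Y)
    ginf = np.zeros(L.N_Y)
    gtau = np.full(L.N_Y, -1.0)
    cur = np.zeros(L.N_CUR)
    fib_block(y, dy, ginf, gtau, cur, i_external_pa)
    dstate = np.array([
        dy[L.FIB_V],
        (ginf[L.FIB_R] - state[1]) / gtau[L.FIB_R],
        (ginf[L.FIB_S] - state[2]) / gtau[L.FIB_S],
    ])
    currents = {
        "IKv": cur[L.C_FIB_IKV],
        "IKir": cur[L.C_FIB_IKIR],
        "INaK": cur[L.C_FIB_INAK],
        "IbNa": cur[L.C_FIB_IBNA],
    }
    return dstate, currents
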