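"""Channel library for composable custom cells.

Each entry names a membrane channel taken from one of four source cell
types (hCIC, hMSC, CF, hCM) together with its baseline maximal conductance
density.  hCM channels reuse the cardiomyocyte formulations verbatim; the
non-excitable channel kinetics are Hodgkin-Huxley reconstructions of the
published source models (delayed rectifier / inward rectifier / BK-type
Ca2+-activated K+ / transient outward / small Na+ and L-type components),
with magnitudes chosen to reproduce the weakly polarized, non-excitable
electrophysiology of those cells.  Leakage currents of the source models
are deliberately not part of the library.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from numba import njit

from .. import layout as L

# Baseline maximal conductance densities, indexed by the channel enum in
# ``layout``.  hCM entries are in mS/uF (the L-type entry is a permeability);
# all others in nS/pF.  Numerically mS/uF == nS/pF.
BASELINE_DENSITY = [
    14.838,    # hcm_na
    0.0075,    # hcm_nal
    0.02,      # hcm_to
    0.0001,    # hcm_cal (permeability)
    0.046,     # hcm_kr
    0.0034,    # hcm_ks
    0.1908,    # hcm_k1
    0.05,      # hcic_na
    0.025,     # hcic_kir
    0.10,      # hcic_bk
    0.075,     # hcic_to
    0.05,      # hmsc_to
    0.01,      # hmsc_to_ss
    0.025,     # hmsc_na
    0.01,      # hmsc_cal
    0.05,      # hmsc_kca
    0.075,     # hmsc_dr
    0.25,      # cf_kv
    0.4822,    # cf_kir
    2.002,     # cf_nak (pA/pF pump magnitude)
    0.0125,    # passive_leak (ohmic, reversal 0 mV; 0.5 nS whole-cell baseline)
]

# Ohmic leak reversal for the purely passive cell variant (mV)
PASSIVE_LEAK_EREV = 0.0


@dataclass(frozen=True)
class ChannelDescriptor:
    """One roster entry: identity, source cell type, baseline conductance."""

    name: str
    source: str          # hcic | hmsc | cf | hcm
    index: int           # position in the layout channel enum
    baseline: float      # maximal conductance density (nS/pF or model-native)

    def __post_init__(self):
        if self.source not in ("hcic", "hmsc", "cf", "hcm", "passive"):
            raise ValueError(f"unknown source cell type {self.source!r}")
        if self.baseline < 0:
            raise ValueError("baseline conductance must be >= 0")


def _mk(name: str) -> ChannelDescriptor:
    idx = L.CHANNEL_NAMES.index(name)
    return ChannelDescriptor(name=name, source=name.split("_")[0],
                             index=idx, baseline=BASELINE_DENSITY[idx])


CHANNEL_LIBRARY: dict[str, ChannelDescriptor] = {n: _mk(n) for n in L.CHANNEL_NAMES}


# --------------------------------------------------- reconstructed kinetics

@njit(cache=True)
def hcic_bk_rates(v):
    # BK at resting intracellular Ca2+: half-activation far depolarized
    xinf = 1.0 / (1.0 + math.exp(-(v - 60.0) / 20.0))
    taux = 8.0
    return xinf, taux


@njit(cache=True)
def hcic_to_rates(v):
    ainf = 1.0 / (1.0 + math.exp(-(v - 5.0) / 14.0))
    taua = 5.0
    iinf = 1.0 / (1.0 + math.exp((v + 30.0) / 6.0))
    taui = 40.0
    return ainf, taua, iinf, taui


@njit(cache=True)
def hmsc_to_rates(v):
    ainf = 1.0 / (1.0 + math.exp(-(v - 10.0) / 15.0))
    taua = 6.0
    iinf = 1.0 / (1.0 + math.exp((v + 25.0) / 7.0))
    taui = 60.0
    return ainf, taua, iinf, taui


@njit(cache=True)
def hmsc_cal_rates(v):
    dinf = 1.0 / (1.0 + math.exp(-(v + 8.0) / 7.5))
    taud = 0.6 + 1.0 / (math.exp(-0.05 * (v + 6.0)) + math.exp(0.09 * (v + 14.0)))
    finf = 1.0 / (1.0 + math.exp((v + 20.0) / 7.0))
    tauf = 80.0
    return dinf, taud, finf, tauf


@njit(cache=True)
def hmsc_kca_rates(v):
    # BK-type at resting intracellular Ca2+
    xinf = 1.0 / (1.0 + math.exp(-(v - 60.0) / 18.0))
    taux = 10.0
    return xinf, taux


@njit(cache=True)
def hmsc_dr_rates(v):
    xinf = 1.0 / (1.0 + math.exp(-(v - 10.0) / 14.0))
    taux = 250.0
    return xinf, taux
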