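"""State vector helpers for the cardiomyocyte block."""

from __future__ import annotations

import numpy as np

from .. import layout as L

STATE_NAMES = [
    "v", "nai", "nass", "ki", "kss", "cai", "cass", "cansr", "cajsr",
    "m", "h", "j", "mL", "hL", "hLp",
    "a", "iF", "iS", "ap", "iFp", "iSp",
    "d", "ff", "fs", "fcaf", "fcas", "jca", "nca", "ffp", "fcafp",
    "xrf", "xrs", "xs1", "xs2", "xk1",
    "Jrelnp", "Jrelp", "CaMKt",
]

# gating variables bounded in [0, 1]
GATE_INDICES = list(range(L.IM, L.IXK1 + 1))
# strictly positive concentrations
CONC_INDICES = [L.INAI, L.INASS, L.IKI, L.IKSS, L.ICAI, L.ICASS, L.ICANSR, L.ICAJSR]


def initial_state() -> np.ndarray:
    """Published resting state of the endocardial cell (fast Na+ gates use
    their ten Tusscher steady-state values at rest).  Long pacing to beat
    500 makes results insensitive to these values."""
    y = np.zeros(L.N_CM)
    y[L.IV] = -87.5
    y[L.INAI] = 7.23
    y[L.INASS] = 7.23
    y[L.IKI] = 143.79
    y[L.IKSS] = 143.79
    y[L.ICAI] = 8.54e-5
    y[L.ICASS] = 8.43e-5
    y[L.ICANSR] = 1.61
    y[L.ICAJSR] = 1.56
    y[L.IM] = 1.05e-3
    y[L.IH] = 0.754
    y[L.IJ] = 0.751
    y[L.IML] = 1.94e-4
    y[L.IHL] = 0.496
    y[L.IHLP] = 0.266
    y[L.IA] = 1.01e-3
    y[L.IIF] = 0.9996
    y[L.IIS] = 0.5896
    y[L.IAP] = 5.16e-4
    y[L.IIFP] = 0.9996
    y[L.IISP] = 0.6419
    y[L.ID] = 2.43e-9
    y[L.IFF] = 1.0
    y[L.IFS] = 0.9107
    y[L.IFCAF] = 1.0
    y[L.IFCAS] = 0.9998
    y[L.IJCA] = 0.99997
    y[L.INCA] = 2.67e-3
    y[L.IFFP] = 1.0
    y[L.IFCAFP] = 1.0
    y[L.IXRF] = 8.27e-6
    y[L.IXRS] = 0.4533
    y[L.IXS1] = 0.2705
    y[L.IXS2] = 1.96e-4
    y[L.IXK1] = 0.9968
    y[L.IJRELNP] = 2.54e-5
    y[L.IJRELP] = 3.17e-7
    y[L.ICAMKT] = 0.0124
    return y


def validate_state(y: np.ndarray) -> None:
    """Raise ``ValueError`` naming the first offending variable."""
    if y.shape[0] < L.N_CM:
        raise ValueError(f"state vector must have at least {L.N_CM} entries")
    for i in range(L.N_CM):
        if not np.isfinite(y[i]):
            raise ValueError(f"non-finite state entry {STATE_NAMES[i]!r} = {y[i]}")
    for i in GATE_INDICES:
        if i in (L.IJRELNP, L.IJRELP):
            continue
        if not (-1e-9 <= y[i] <= 1.0 + 1e-9):
            raise ValueError(f"gating variable {STATE_NAMES[i]!r} out of [0,1]: {y[i]}")
    for i in CONC_INDICES:
        if not (y[i] > 0.0):
            raise ValueError(f"concentration {STATE_NAMES[i]!r} must be positive: {y[i]}")
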