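"""Python-facing right-hand side of the single cardiomyocyte."""

from __future__ import annotations

import numpy as np

from .. import layout as L
from .ord import cm_block, pack_cm_params
from .parameters import CMParameters
from .state import validate_state


def ord_rhs(state: np.ndarray, params: CMParameters, i_external: float = 0.0):
    """Time derivative of the cardiomyocyte state plus a labeled current
    breakdown.

    ``i_external`` (stimulus plus gap-junction load, uA/uF) enters the
    voltage equation only (and the K+ bookkeeping that carries it).
    Raises ``ValueError`` naming the offending variable for invalid states.
    """
    state = np.asarray(state, dtype=float)
    validate_state(state)
    y = np.zeros(L.N_Y)
    y[:L.N_CM] = state[:L.N_CM]
    dy = np.zeros(L.N_Y)
    ginf = np.zeros(L.N_Y)
    gtau = np.full(L.N_Y, -1.0)
    cur = np.zeros(L.N_CUR)
    cm_block(y, dy, ginf, gtau, cur, pack_cm_params(params), i_external)
    dstate = dy[:L.N_CM].copy()
    for i in range(L.N_CM):
        if gtau[i] > 0.0:
            dstate[i] = (ginf[i] - y[i]) / gtau[i]
    breakdown = {name: cur[i] for i, name in enumerate(L.CURRENT_NAMES[:18])}
    return dstate, breakdown
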