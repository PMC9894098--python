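"""Independent integration route: stiff adaptive (BDF) solution of the same
coupled system, used to validate the fixed-step Rush-Larsen integrator.

This route shares the model equations but none of the stepping machinery:
scipy's implicit multistep solver with error control integrates the plain
derivative vector, with the stimulus handled by breaking each beat into an
on-pulse and an off-pulse interval.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import solve_ivp

from .engine import EP_CL, EP_STIM_AMP, EP_STIM_DUR, full_derivs


def integrate_adaptive(y0: np.ndarray, epar: np.ndarray, n_beats: int,
                       rtol: float = 1e-6, atol: float = 1e-8):
    """Pace ``n_beats`` with BDF, sampling every 1 ms.

    Returns (t, Y) with t starting at the first stimulus onset and Y of
    shape (n_states, len(t)); the last sample sits at n_beats*CL.
    """
    cl = float(epar[EP_CL])
    amp = float(epar[EP_STIM_AMP])
    dur = float(epar[EP_STIM_DUR])

    y = np.asarray(y0, dtype=float).copy()
    ts_all = []
    ys_all = []
    for b in range(n_beats):
        offset = b * cl
        # stimulus on: record t=0 only (sub-ms pulse)
        sol1 = solve_ivp(lambda t, yy: full_derivs(yy, epar, amp),
                         (0.0, dur), y, method="BDF", rtol=rtol, atol=atol,
                         t_eval=np.array([0.0, dur]), max_step=0.1)
        if not sol1.success:
            raise RuntimeError(f"adaptive integration failed: {sol1.message}")
        ts_all.append(np.array([offset]))
        ys_all.append(sol1.y[:, :1])
        y = sol1.y[:, -1]
        # stimulus off: record every whole ms up to cl-1, end state at cl
        t_eval = np.append(np.arange(1.0, cl, 1.0), cl)
        sol2 = solve_ivp(lambda t, yy: full_derivs(yy, epar, 0.0),
                         (dur, cl), y, method="BDF", rtol=rtol, atol=atol,
                         t_eval=t_eval)
        if not sol2.success:
            raise RuntimeError(f"adaptive integration failed: {sol2.message}")
        ts_all.append(t_eval[:-1] + offset)
        ys_all.append(sol2.y[:, :-1])
        y = sol2.y[:, -1]
    ts_all.append(np.array([n_beats * cl]))
    ys_all.append(y[:, None])
    return np.concatenate(ts_all), np.concatenate(ys_all, axis=1)
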