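"""Compiled integrator for the coupled cardiomyocyte / fibroblast /
custom-cell system.

One flat parameter vector configures the whole system so a single compiled
kernel serves every experiment.  Gate variables advance with exact
exponential (Rush-Larsen) updates; voltages, concentrations and the CaMK
state advance with forward Euler on a deterministic piecewise step-size
schedule (fine during the upstroke/release phase of each paced beat, coarse
in diastole).  The schedule is part of the solver settings, so identical
configurations yield bit-identical traces.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .. import layout as L
from ..cardiomyocyte.ord import N_PCM, P_CCM, cm_block
from ..support_cells.custom_cell import cu_block
from ..support_cells.fibroblast import fib_block

# engine parameter vector layout
EP_STIM_AMP = N_PCM + 0
EP_STIM_DUR = N_PCM + 1
EP_CL = N_PCM + 2
EP_N_FIB = N_PCM + 3
EP_G_FIB = N_PCM + 4
EP_N_CU = N_PCM + 5
EP_G_GAP = N_PCM + 6
EP_HAS_CU = N_PCM + 7
EP_DENS0 = N_PCM + 8
N_EPAR = EP_DENS0 + L.N_CHANNELS

# default step-size schedule (ms boundaries within each beat -> dt);
# finest during the upstroke, coarse in diastole
DEFAULT_SEG_BOUNDS = (0.0, 5.0, 20.0, 200.0, 500.0)
DEFAULT_SEG_DTS = (0.002, 0.01, 0.02, 0.05, 0.2)


@njit(cache=True)
def eval_system(y, epar, istim, dy, ginf, gtau, cur):
    vcm = y[L.IV]
    ccm = epar[P_CCM]
    igap_fib = 0.0
    igap_cu = 0.0
    n_fib = epar[EP_N_FIB]
    if n_fib > 0.0:
        igap_fib = n_fib * epar[EP_G_FIB] * (vcm - y[L.FIB_V])
    if epar[EP_HAS_CU] > 0.0:
        igap_cu = epar[EP_N_CU] * epar[EP_G_GAP] * (vcm - y[L.CU_V])

    i_ext = istim + (igap_fib + igap_cu) / ccm
    cm_block(y, dy, ginf, gtau, cur, epar[:N_PCM], i_ext)

    if n_fib > 0.0:
        fib_block(y, dy, ginf, gtau, cur, epar[EP_G_FIB] * (y[L.FIB_V] - vcm))
    if epar[EP_HAS_CU] > 0.0:
        cu_block(y, dy, ginf, gtau, cur, epar[EP_DENS0:EP_DENS0 + L.N_CHANNELS],
                 epar[EP_G_GAP] * (y[L.CU_V] - vcm))

    cur[L.C_ISTIM] = istim
    cur[L.C_IGAP_FIB] = igap_fib
    cur[L.C_IGAP_CU] = igap_cu
    cur[L.C_IGAP_CU_ONE] = epar[EP_G_GAP] * (vcm - y[L.CU_V]) if epar[EP_HAS_CU] > 0.0 else 0.0


@njit(cache=True)
def full_derivs(y, epar, istim):
    """Plain derivative vector (gates converted from inf/tau form); used by
    the independent stiff adaptive integration route."""
    dy = np.zeros(L.N_Y)
    ginf = np.zeros(L.N_Y)
    gtau = np.full(L.N_Y, -1.0)
    cur = np.zeros(L.N_CUR)
    eval_system(y, epar, istim, dy, ginf, gtau, cur)
    for i in range(L.N_Y):
        if gtau[i] > 0.0:
            dy[i] = (ginf[i] - y[i]) / gtau[i]
    return dy


@njit(cache=True)
def _advance(y, dt, dy, ginf, gtau):
    for i in range(L.N_Y):
        if gtau[i] > 0.0:
            y[i] = ginf[i] + (y[i] - ginf[i]) * math.exp(-dt / gtau[i])
        elif dy[i] != 0.0:
            y[i] = y[i] + dt * dy[i]


@njit(cache=True)
def run_paced(y0, epar, n_beats, record_beats, seg_bounds, seg_dts):
    """Pace for ``n_beats`` cycles, recording the last ``record_beats`` on a
    1 ms grid.

    Returns (times, vars, currents, y_final, status) where ``vars`` columns
    are (Vm_cm, Vm_fib, Vm_custom, Cai) and status is 0 on success, 1 if the
    state went non-finite (integration failure).
    """
    cl = epar[EP_CL]
    amp = epar[EP_STIM_AMP]
    sdur = epar[EP_STIM_DUR]
    cl_ms = int(round(cl))

    n_rec = record_beats * cl_ms + 1
    rec_t = np.empty(n_rec)
    rec_v = np.empty((n_rec, 4))
    rec_c = np.empty((n_rec, L.N_CUR))

    y = y0.copy()
    dy = np.zeros(L.N_Y)
    ginf = np.zeros(L.N_Y)
    gtau = np.full(L.N_Y, -1.0)
    cur = np.zeros(L.N_CUR)

    n_seg = len(seg_dts)
    rec_idx = 0
    status = 0

    for b in range(n_beats):
        recording = b >= n_beats - record_beats
        beat_offset = (b - (n_beats - record_beats)) * cl_ms
        for s in range(n_seg):
            t0 = seg_bounds[s]
            t1 = seg_bounds[s + 1] if s + 1 < n_seg else cl
            dt = seg_dts[s]
            nsteps = int(round((t1 - t0) / dt))
            steps_per_ms = int(round(1.0 / dt))
            for k in range(nsteps):
                t_in_beat = t0 + k * dt
                istim = amp if t_in_beat < sdur - 1e-9 else 0.0
                eval_system(y, epar, istim, dy, ginf, gtau, cur)
                if recording and k % steps_per_ms == 0:
                    tms = beat_offset + int(round(t0)) + k // steps_per_ms
                    rec_t[rec_idx] = float(tms)
                    rec_v[rec_idx, 0] = y[L.IV]
                    rec_v[rec_idx, 1] = y[L.FIB_V]
                    rec_v[rec_idx, 2] = y[L.CU_V]
                    rec_v[rec_idx, 3] = y[L.ICAI]
                    rec_c[rec_idx] = cur
                    rec_idx += 1
                _advance(y, dt, dy, ginf, gtau)
        if not (math.isfinite(y[L.IV]) and math.isfinite(y[L.ICAI])
                and math.isfinite(y[L.CU_V])):
            status = 1
            break

    if status == 0 and record_beats > 0:
        # closing sample at the end of the final beat
        eval_system(y, epar, 0.0, dy, ginf, gtau, cur)
        rec_t[rec_idx] = float(record_beats * cl_ms)
        rec_v[rec_idx, 0] = y[L.IV]
        rec_v[rec_idx, 1] = y[L.FIB_V]
        rec_v[rec_idx, 2] = y[L.CU_V]
        rec_v[rec_idx, 3] = y[L.ICAI]
        rec_c[rec_idx] = cur
        rec_idx += 1

    return rec_t[:rec_idx], rec_v[:rec_idx], rec_c[:rec_idx], y, status
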