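"""High-level simulation API: assemble the coupled system, pace it, and
extract final-beat waveforms."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .. import layout as L
from ..cardiomyocyte.ord import N_PCM, pack_cm_params
from ..cardiomyocyte.parameters import CMParameters, parameters_for
from ..cardiomyocyte.state import initial_state
from ..support_cells.custom_cell import CustomCellSpec, cu_initial_state
from ..support_cells.fibroblast import fib_initial_state
from .config import CouplingConfig
from .engine import (
    DEFAULT_SEG_BOUNDS, DEFAULT_SEG_DTS, EP_CL, EP_DENS0, EP_G_FIB, EP_G_GAP,
    EP_HAS_CU, EP_N_CU, EP_N_FIB, EP_STIM_AMP, EP_STIM_DUR, N_EPAR, run_paced,
)

WINDOW_MS = 500  # analysis window of the final beat


class SimulationError(RuntimeError):
    """Integration failure; carries the configuration for GA bookkeeping."""

    def __init__(self, message, config=None, spec=None):
        super().__init__(message)
        self.config = config
        self.spec = spec


@dataclass(frozen=True)
class Trace:
    """Uniform 1 ms traces of the recorded beats."""

    t: np.ndarray               # ms, 0 at the first recorded stimulus onset
    vm_cm: np.ndarray           # mV
    vm_fib: np.ndarray          # mV
    vm_custom: np.ndarray       # mV
    cai: np.ndarray             # mM
    currents: dict = field(repr=False, default_factory=dict)
    cycle_length_ms: float = 1000.0
    final_state: np.ndarray | None = None

    def __post_init__(self):
        n = self.t.shape[0]
        for name in ("vm_cm", "vm_fib", "vm_custom", "cai"):
            if getattr(self, name).shape[0] != n:
                raise ValueError("trace series must share one grid")
        if n > 1 and not np.allclose(np.diff(self.t), self.t[1] - self.t[0]):
            raise ValueError("trace grid must be uniform")

    def to_frame(self) -> pd.DataFrame:
        data = {"time_ms": self.t, "Vm_mV": self.vm_cm, "Vm_fib_mV": self.vm_fib,
                "Vm_custom_mV": self.vm_custom, "Cai_mM": self.cai}
        data.update(self.currents)
        return pd.DataFrame(data)


@dataclass(frozen=True)
class BeatWaveforms:
    """Final-beat AP and CaT over [0, 500] ms at 1 ms (501 samples)."""

    ap: np.ndarray   # mV
    cat: np.ndarray  # mM

    def __post_init__(self):
        if self.ap.shape != (WINDOW_MS + 1,) or self.cat.shape != (WINDOW_MS + 1,):
            raise ValueError(f"waveforms must have exactly {WINDOW_MS + 1} samples")

    @property
    def t(self) -> np.ndarray:
        return np.arange(WINDOW_MS + 1, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ms": self.t, "Vm_mV": self.ap, "Cai_mM": self.cat})


def build_epar(config: CouplingConfig, spec: CustomCellSpec | None,
               cm_params: CMParameters | None = None) -> np.ndarray:
    if cm_params is None:
        cm_params = parameters_for(config.phenotype)
    epar = np.zeros(N_EPAR)
    epar[:N_PCM] = pack_cm_params(cm_params)
    epar[EP_STIM_AMP] = config.stim_amp
    epar[EP_STIM_DUR] = config.stim_dur
    epar[EP_CL] = config.cycle_length_ms
    epar[EP_N_FIB] = float(config.n_fibroblasts)
    epar[EP_G_FIB] = config.g_fib_gap
    if spec is not None:
        if config.n_custom < 1:
            raise ValueError("n_custom must be >= 1 when a custom cell is present")
        epar[EP_N_CU] = float(config.n_custom)
        epar[EP_G_GAP] = config.g_gap
        epar[EP_HAS_CU] = 1.0
        epar[EP_DENS0:EP_DENS0 + L.N_CHANNELS] = spec.density_vector()
    elif config.n_custom > 0:
        raise ValueError("spec must be provided when n_custom >= 1")
    return epar


def assemble_initial_state(y0_cm: np.ndarray | None = None,
                           vm_custom: float | None = None) -> np.ndarray:
    y = np.zeros(L.N_Y)
    y[:L.N_CM] = initial_state() if y0_cm is None else y0_cm[:L.N_CM]
    y[L.FIB_V:L.FIB_S + 1] = fib_initial_state()
    y[L.CU0:] = cu_initial_state()
    if vm_custom is not None:
        y[L.CU_V] = vm_custom
    return y


def simulate(config: CouplingConfig, spec: CustomCellSpec | None = None, *,
             cm_params: CMParameters | None = None,
             y0: np.ndarray | None = None,
             seg_bounds=DEFAULT_SEG_BOUNDS, seg_dts=DEFAULT_SEG_DTS) -> Trace:
    """Pace the coupled system and return recorded traces.

    ``y0`` may supply a full system state (e.g. a pre-paced steady state) to
    continue from; otherwise published resting states are used.
    """
    epar = build_epar(config, spec, cm_params)
    if y0 is None:
        y = assemble_initial_state()
    else:
        y = np.asarray(y0, dtype=float).copy()
        if y.shape[0] != L.N_Y:
            raise ValueError(f"y0 must have {L.N_Y} entries")
    sb = np.asarray(seg_bounds, dtype=float)
    sd = np.asarray(seg_dts, dtype=float)
    if sb.shape[0] != sd.shape[0]:
        raise ValueError("one dt per schedule segment required")
    t, v, c, y_final, status = run_paced(
        y, epar, config.n_beats, config.record_beats, sb, sd)
    if status != 0:
        raise SimulationError("integration failure (non-finite state)",
                              config=config, spec=spec)
    currents = {name: c[:, i].copy() for i, name in enumerate(L.CURRENT_NAMES)}
    return Trace(t=t, vm_cm=v[:, 0].copy(), vm_fib=v[:, 1].copy(),
                 vm_custom=v[:, 2].copy(), cai=v[:, 3].copy(),
                 currents=currents, cycle_length_ms=config.cycle_length_ms,
                 final_state=y_final)


def extract_final_beat(trace: Trace) -> BeatWaveforms:
    """AP and CaT of the final recorded beat over [0, 500] ms from stimulus
    onset on the 1 ms grid."""
    cl = int(round(trace.cycle_length_ms))
    need = WINDOW_MS + 1
    if trace.t.shape[0] < need:
        raise ValueError("trace shorter than the 500 ms analysis window")
    # onset of the final beat within the recorded span
    n_full_beats = (trace.t.shape[0] - 1) // cl
    if n_full_beats < 1:
        raise ValueError("trace does not cover a full pacing cycle")
    start = (n_full_beats - 1) * cl
    if start + need > trace.t.shape[0]:
        raise ValueError("trace does not cover the final-beat window")
    sl = slice(start, start + need)
    return BeatWaveforms(ap=trace.vm_cm[sl].copy(), cat=trace.cai[sl].copy())


def waveforms_to_csv(wf: BeatWaveforms, path: str | Path) -> None:
    wf.to_frame().to_csv(path, index=False)


def waveforms_from_csv(path: str | Path) -> BeatWaveforms:
    df = pd.read_csv(path)
    return BeatWaveforms(ap=df["Vm_mV"].to_numpy(), cat=df["Cai_mM"].to_numpy())
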