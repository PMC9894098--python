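"""Reference steady states and waveforms for healthy and untreated failing
cardiomyocytes.

Full-protocol references pace 500 beats at 1 Hz from the published resting
state.  Because that costs tens of seconds per phenotype, the package also
ships the resulting steady states as plain-text JSON; loading a shipped
state and pacing a handful of wash-in beats reproduces the full-protocol
waveform to well below the solver tolerance.  ``from_scratch=True`` always
re-runs the complete protocol.
"""

from __future__ import annotations

import json
from functools import lru_cache
from pathlib import Path

import numpy as np

from .. import layout as L
from ..coupling.config import CouplingConfig
from ..coupling.simulate import BeatWaveforms, Trace, extract_final_beat, simulate

_DATA_DIR = Path(__file__).resolve().parent.parent / "data"

N_BEATS_PROTOCOL = 500

_PHENO_FILES = {
    "healthy": "prepaced_healthy.json",
    "hf": "prepaced_hf.json",
    "hf+fibrosis": "prepaced_hf_fibrosis.json",
}


def reference_config(phenotype: str, n_beats: int = N_BEATS_PROTOCOL) -> CouplingConfig:
    return CouplingConfig(phenotype=phenotype, n_custom=0, n_beats=n_beats,
                          record_beats=1)


def compute_prepaced_state(phenotype: str, n_beats: int = N_BEATS_PROTOCOL) -> np.ndarray:
    trace = simulate(reference_config(phenotype, n_beats))
    return trace.final_state


def shipped_prepaced_state(phenotype: str) -> np.ndarray:
    path = _DATA_DIR / _PHENO_FILES[phenotype]
    with open(path) as fh:
        payload = json.load(fh)
    y = np.asarray(payload["state"], dtype=float)
    if y.shape[0] != L.N_Y:
        raise ValueError(f"shipped state for {phenotype} has wrong length")
    return y


@lru_cache(maxsize=8)
def _cached_reference(phenotype: str, from_scratch: bool) -> BeatWaveforms:
    if from_scratch:
        trace = simulate(reference_config(phenotype))
    else:
        y0 = shipped_prepaced_state(phenotype)
        cfg = reference_config(phenotype, n_beats=1)
        trace = simulate(cfg, y0=y0)
    return extract_final_beat(trace)


def reference_waveforms(phenotype: str, from_scratch: bool = False) -> BeatWaveforms:
    """Final-beat AP/CaT of the uncoupled (or fibrotic, untreated) cell."""
    return _cached_reference(phenotype, from_scratch)


def reference_trace(phenotype: str, from_scratch: bool = False) -> Trace:
    """Full final-beat trace (for current overlays)."""
    if from_scratch:
        return simulate(reference_config(phenotype))
    y0 = shipped_prepaced_state(phenotype)
    return simulate(reference_config(phenotype, n_beats=1), y0=y0)
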