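"""Genome evaluation: couple a candidate custom cell to the failing
cardiomyocyte, pace, and score the final beat against the references.

The full protocol paces every candidate 500 beats from rest.  The desk
protocol starts from the shipped untreated steady state and paces a wash-in
window instead; the final beat is insensitive to the starting point well
before 500 beats, and the wash-in length is configurable so the trade-off
is explicit everywhere it is used.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .. import layout as L
from ..coupling.config import CouplingConfig
from ..coupling.simulate import extract_final_beat, simulate
from ..ga.genome import G_GAP_BASELINE_NS
from ..metrics import ObjectiveScores, normalized_rmse
from ..support_cells.custom_cell import CustomCellSpec, cu_initial_state
from ..support_cells.presets import roster as roster_for
from .references import (
    N_BEATS_PROTOCOL, reference_waveforms, shipped_prepaced_state,
)

DEFAULT_WASHIN_BEATS = 50

# Coarse step-size schedule for wash-in beats (nothing is recorded there);
# the final recorded beat always uses the default fine schedule.  Scores
# agree with an all-fine integration to ~3 decimal places.
WASHIN_SEG_BOUNDS = (0.0, 5.0, 20.0, 200.0, 500.0)
WASHIN_SEG_DTS = (0.005, 0.02, 0.1, 0.2, 0.5)


@dataclass(frozen=True)
class EvalProtocol:
    """How each candidate is simulated and scored."""

    phenotype: str = "hf+fibrosis"
    washin_beats: int = DEFAULT_WASHIN_BEATS
    from_rest: bool = False          # True = full 500-beat protocol from rest
    searchable: tuple[str, ...] | None = None
    # roster channels whose scaling the genome varies; None means every
    # roster channel is searchable, () means only (G_gap, n) are searched

    def n_beats(self) -> int:
        return N_BEATS_PROTOCOL if self.from_rest else self.washin_beats


def genome_to_spec(genome: np.ndarray, roster: tuple[str, ...],
                   searchable: tuple[str, ...] | None = None
                   ) -> tuple[CustomCellSpec, float, int]:
    """Split a genome row into (spec, g_gap nS, n_custom).

    With a ``searchable`` subset, the genome carries one scaling per
    searchable channel (in roster order) and the remaining roster channels
    stay at baseline (scaling 1)."""
    search = roster if searchable is None else searchable
    n_search = len(search)
    scalings = []
    idx = {name: k for k, name in enumerate(search)}
    for name in roster:
        scalings.append(float(genome[idx[name]]) if name in idx else 1.0)
    g_gap = float(genome[n_search]) * G_GAP_BASELINE_NS
    n_custom = int(round(genome[n_search + 1]))
    return CustomCellSpec(roster=roster, scalings=tuple(scalings)), g_gap, n_custom


def evaluate_genome(genome: np.ndarray, roster: tuple[str, ...],
                    protocol: EvalProtocol) -> ObjectiveScores:
    wf = simulate_genome(genome, roster, protocol)
    healthy = reference_waveforms("healthy")
    untreated = reference_waveforms(protocol.phenotype)
    return normalized_rmse(wf, healthy, untreated)


def simulate_genome(genome: np.ndarray, roster: tuple[str, ...],
                    protocol: EvalProtocol, record_beats: int = 1):
    """Final-beat waveforms of the treated cardiomyocyte (raises
    SimulationError on integrator failure)."""
    spec, g_gap, n_custom = genome_to_spec(genome, roster, protocol.searchable)
    y0 = None
    if not protocol.from_rest:
        y0 = shipped_prepaced_state(protocol.phenotype).copy()
        y0[L.CU0:] = cu_initial_state()
    n_total = protocol.n_beats()
    n_washin = max(n_total - record_beats, 0)
    if n_washin > 0:
        washin_cfg = CouplingConfig(phenotype=protocol.phenotype, n_custom=n_custom,
                                    g_gap=g_gap, n_beats=n_washin, record_beats=0)
        tr = simulate(washin_cfg, spec, y0=y0,
                      seg_bounds=WASHIN_SEG_BOUNDS, seg_dts=WASHIN_SEG_DTS)
        y0 = tr.final_state
    cfg = CouplingConfig(phenotype=protocol.phenotype, n_custom=n_custom,
                         g_gap=g_gap, n_beats=record_beats,
                         record_beats=record_beats)
    trace = simulate(cfg, spec, y0=y0)
    if record_beats > 1:
        return trace
    return extract_final_beat(trace)


def make_evaluator(roster_name: str, protocol: EvalProtocol):
    """Evaluator closure for the GA driver."""
    roster = roster_for(roster_name)
    # warm the reference cache so evaluation is reference-invariant
    reference_waveforms("healthy")
    reference_waveforms(protocol.phenotype)

    def _eval(genome: np.ndarray) -> ObjectiveScores:
        return evaluate_genome(genome, roster, protocol)

    return _eval
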