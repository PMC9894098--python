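"""Experiment execution: GA reproductions and the engineered-cell minimum
RMSE search, plus result bundles on disk."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ..coupling.simulate import SimulationError, waveforms_to_csv
from ..ga.genome import (
    G_GAP_BASELINE_NS, N_CUSTOM_MAX, N_CUSTOM_MIN, SCALING_HIGH, SCALING_LOW,
)
from ..ga.run import GenerationLog, run_ga
from ..metrics import ObjectiveScores, WORST_SCORES, ap_metrics, cat_metrics
from ..support_cells.presets import roster as roster_for
from .evaluation import EvalProtocol, evaluate_genome, make_evaluator, simulate_genome
from .presets import ExperimentPreset, experiment
from .references import reference_waveforms


def run_experiment(preset: ExperimentPreset | str, seed: int, *,
                   population: int | None = None, generations: int | None = None,
                   washin_beats: int = 50, from_rest: bool = False,
                   out_dir: str | Path | None = None,
                   n_trace_accepted: int = 5,
                   progress=None) -> GenerationLog:
    """Run one named GA experiment and (optionally) persist the bundle:
    per-generation tables, accepted-parameter summary, reference overlays
    and final-beat waveforms for a subset of accepted individuals."""
    if isinstance(preset, str):
        preset = experiment(preset)
    channels = preset.genome_channels()
    if not channels:
        raise ValueError(
            f"preset {preset.name!r} has no searchable channel scaling; "
            "use min_rmse_search for the control engineered-cell groups")
    protocol = preset.protocol(washin_beats, from_rest)
    evaluator = make_evaluator(preset.roster_name, protocol)
    cfg = preset.ga_config(seed, population, generations)
    log = run_ga(cfg, channels, evaluator, progress=progress)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        log.save(out)
        log.accepted_summary().to_csv(out / "accepted_summary.csv", index=False)
        waveforms_to_csv(reference_waveforms("healthy"), out / "reference_healthy.csv")
        waveforms_to_csv(reference_waveforms(preset.phenotype),
                         out / "reference_untreated.csv")
        _dump_accepted_waveforms(log, preset, protocol, out, n_trace_accepted)
    return log


def _dump_accepted_waveforms(log: GenerationLog, preset: ExperimentPreset,
                             protocol: EvalProtocol, out: Path, n_max: int) -> None:
    acc = log.accepted_final()
    roster = roster_for(preset.roster_name)
    cols = [c for c in acc.columns
            if c.startswith("scale_") or c in ("g_gap_scale", "n_custom")]
    rows = []
    for rank, (_, row) in enumerate(acc.head(n_max).iterrows()):
        genome = row[cols].to_numpy(dtype=float)
        try:
            wf = simulate_genome(genome, roster, protocol)
        except SimulationError:
            continue
        waveforms_to_csv(wf, out / f"accepted_{rank:02d}_waveforms.csv")
        apm = ap_metrics(wf)
        ctm = cat_metrics(wf)
        rows.append({"rank": rank, **{c: row[c] for c in cols},
                     "apd50": apm.apd50, "apd90": apm.apd90,
                     "peak_vm": apm.peak_vm, "upstroke": apm.upstroke_velocity,
                     "rmp": apm.rmp, "cat_peak": ctm.peak,
                     "cat_diastolic": ctm.diastolic, "cat_amplitude": ctm.amplitude,
                     "tau50": ctm.tau50, "tau90": ctm.tau90})
    if rows:
        pd.DataFrame(rows).to_csv(out / "accepted_metrics.csv", index=False)


@dataclass(frozen=True)
class SearchResult:
    genome: np.ndarray
    channels: tuple[str, ...]
    scores: ObjectiveScores        # at the total-RMSE minimizer
    n_evaluations: int
    table: pd.DataFrame

    @property
    def min_rmse_ap(self) -> float:
        """Minimum AP RMSE pooled over every evaluation."""
        return float(self.table["rmse_ap"].min())

    @property
    def min_rmse_cat(self) -> float:
        """Minimum CaT RMSE pooled over every evaluation."""
        return float(self.table["rmse_cat"].min())


def min_rmse_search(preset: ExperimentPreset | str, budget: int, seed: int, *,
                    washin_beats: int = 50, from_rest: bool = False,
                    refine_rounds: int = 2) -> SearchResult:
    """Minimize rmse_ap + rmse_cat for the engineered-cell presets over
    (n_custom, G_gap scale[, channel scaling]) with a budgeted deterministic
    grid followed by local log-space refinement; the minimum is pooled over
    every evaluation."""
    if isinstance(preset, str):
        preset = experiment(preset)
    if budget < 1:
        raise ValueError("search budget must be >= 1")
    channels = preset.genome_channels()   # () for the control groups
    protocol = preset.protocol(washin_beats, from_rest)
    roster = roster_for(preset.roster_name)

    n_ch = len(channels)
    n_n = N_CUSTOM_MAX - N_CUSTOM_MIN + 1
    # allocate the budget across a log grid in each continuous dimension;
    # a pure log grid over [1e-4, 10] concentrates on vanishing scalings, so
    # the axis is the union of the full-range grid and an upper-decade grid
    # around the baseline where the conductances actually act
    n_cont_dims = 1 + n_ch
    pts = max(2, int(round((budget / n_n) ** (1.0 / n_cont_dims))))
    grid_cont = np.unique(np.concatenate([
        np.geomspace(SCALING_LOW, SCALING_HIGH, pts),
        np.geomspace(0.5, SCALING_HIGH, max(pts, 3)),
    ]))

    rows = []
    best = None
    n_eval = 0
    axes = [grid_cont] * n_cont_dims
    mesh = np.meshgrid(*axes, indexing="ij") if n_cont_dims else []
    flat = [m.ravel() for m in mesh]
    for n_custom in range(N_CUSTOM_MIN, N_CUSTOM_MAX + 1):
        for i in range(flat[0].shape[0] if flat else 1):
            genome = np.empty(n_ch + 2)
            for d in range(n_ch):
                genome[d] = flat[d][i]
            genome[n_ch] = flat[n_ch][i]
            genome[n_ch + 1] = n_custom
            try:
                sc = evaluate_genome(genome, roster, protocol)
            except SimulationError:
                sc = WORST_SCORES
            n_eval += 1
            rows.append({**{f"scale_{c}": genome[d] for d, c in enumerate(channels)},
                         "g_gap_scale": genome[n_ch], "n_custom": n_custom,
                         "rmse_ap": sc.rmse_ap, "rmse_cat": sc.rmse_cat,
                         "total": sc.total})
            if best is None or sc.total < best[1].total:
                best = (genome.copy(), sc)

    # local refinement in log space around the incumbent (n_custom fixed)
    for r in range(refine_rounds):
        center = best[0]
        width = 3.0 / (2.0 ** r)
        axes = []
        for d in range(n_cont_dims):
            lo = max(SCALING_LOW, center[d] / width)
            hi = min(SCALING_HIGH, center[d] * width)
            axes.append(np.geomspace(lo, hi, 5))
        mesh = np.meshgrid(*axes, indexing="ij")
        flat = [m.ravel() for m in mesh]
        for i in range(flat[0].shape[0]):
            genome = np.empty(n_ch + 2)
            for d in range(n_cont_dims):
                genome[d] = flat[d][i]
            genome[n_ch + 1] = center[n_ch + 1]
            try:
                sc = evaluate_genome(genome, roster, protocol)
            except SimulationError:
                sc = WORST_SCORES
            n_eval += 1
            rows.append({**{f"scale_{c}": genome[d] for d, c in enumerate(channels)},
                         "g_gap_scale": genome[n_ch], "n_custom": genome[n_ch + 1],
                         "rmse_ap": sc.rmse_ap, "rmse_cat": sc.rmse_cat,
                         "total": sc.total})
            if sc.total < best[1].total:
                best = (genome.copy(), sc)
    table = pd.DataFrame(rows)
    return SearchResult(genome=best[0], channels=channels, scores=best[1],
                        n_evaluations=n_eval, table=table)


def write_manifest(out: Path, payload: dict) -> None:
    with open(out / "run.json", "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
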