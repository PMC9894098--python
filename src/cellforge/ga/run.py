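"""GA driver: evolve a population of genomes against an objective evaluator.

The evaluator maps one genome row to ObjectiveScores.  Failed simulations
(SimulationError) score worst instead of aborting the run.  Identical
genomes share one cached evaluation (the objective is a pure function of
the genome), so post-elitism copies are free.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from ..coupling.simulate import SimulationError
from ..metrics import ObjectiveScores, WORST_SCORES
from .genome import GAConfig, genome_columns, validate_population
from .operators import crossover, elitism, init_population, mutate, tournament_select

Evaluator = Callable[[np.ndarray], ObjectiveScores]


@dataclass
class GenerationLog:
    roster: tuple[str, ...]
    config: GAConfig
    tables: list[pd.DataFrame] = field(default_factory=list)

    def append(self, generation: int, pop: np.ndarray, scores: list[ObjectiveScores]):
        df = pd.DataFrame(pop, columns=genome_columns(self.roster))
        df.insert(0, "generation", generation)
        df["rmse_ap"] = [s.rmse_ap for s in scores]
        df["rmse_cat"] = [s.rmse_cat for s in scores]
        df["n_pass"] = [s.n_pass for s in scores]
        df["accepted"] = [s.accepted for s in scores]
        self.tables.append(df)

    @property
    def final(self) -> pd.DataFrame:
        return self.tables[-1]

    def acceptance_fraction(self, generation: int = -1) -> float:
        return float(self.tables[generation]["accepted"].mean())

    def accepted_final(self) -> pd.DataFrame:
        return self.final[self.final["accepted"]]

    def accepted_summary(self) -> pd.DataFrame:
        """Median and IQR of every genome parameter over the accepted set of
        the final generation."""
        acc = self.accepted_final()
        cols = genome_columns(self.roster)
        rows = []
        for c in cols:
            q1, med, q3 = (np.percentile(acc[c], [25, 50, 75])
                           if len(acc) else (np.nan, np.nan, np.nan))
            rows.append({"parameter": c, "median": med, "q1": q1, "q3": q3})
        return pd.DataFrame(rows)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for g, df in enumerate(self.tables):
            df.to_csv(out / f"generation_{g:02d}.csv", index=False)
        manifest = {
            "roster": list(self.roster),
            "config": self.config.__dict__,
            "generations": len(self.tables),
            "acceptance_per_generation": [float(df["accepted"].mean())
                                          for df in self.tables],
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)


def _score_population(pop: np.ndarray, evaluator: Evaluator,
                      cache: dict) -> list[ObjectiveScores]:
    scores: list[ObjectiveScores] = []
    for row in pop:
        key = row.tobytes()
        hit = cache.get(key)
        if hit is None:
            try:
                hit = evaluator(row)
            except SimulationError:
                hit = WORST_SCORES
            cache[key] = hit
        scores.append(hit)
    return scores


def run_ga(cfg: GAConfig, roster: tuple[str, ...], evaluator: Evaluator,
           progress: Callable[[str], None] | None = None) -> GenerationLog:
    """Evolve for cfg.generations rounds of selection, crossover, mutation
    and elitism; generation 0 is the scored initial population."""
    if len(roster) < 1:
        raise ValueError("empty channel roster")
    rng = np.random.default_rng(cfg.seed)
    cache: dict = {}
    log = GenerationLog(roster=tuple(roster), config=cfg)

    pop = init_population(cfg.population_size, len(roster), rng)
    scores = _score_population(pop, evaluator, cache)
    log.append(0, pop, scores)
    if progress:
        progress(f"generation 0: acceptance {np.mean([s.accepted for s in scores]):.3f}")

    for g in range(1, cfg.generations + 1):
        prev_pop = pop
        prev_n_pass = np.array([s.n_pass for s in scores])
        prev_total = np.array([s.total for s in scores])
        pop = tournament_select(pop, prev_n_pass, prev_total, rng)
        pop = crossover(pop, cfg.crossover_pair_prob, cfg.crossover_param_prob, rng)
        pop = mutate(pop, cfg.mutation_prob, cfg.mutation_sigma_log, rng)
        validate_population(pop, len(roster))
        scores = _score_population(pop, evaluator, cache)
        n_pass = np.array([s.n_pass for s in scores])
        total = np.array([s.total for s in scores])
        # elites of the parent generation survive into the offspring
        pop, _, _ = elitism(pop, n_pass, total, cfg.elite_frac,
                            elite_pool=(prev_pop, prev_n_pass, prev_total))
        scores = _score_population(pop, evaluator, cache)  # cache hits for copies
        log.append(g, pop, scores)
        if progress:
            progress(f"generation {g}: acceptance "
                     f"{np.mean([s.accepted for s in scores]):.3f}")
    return log
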