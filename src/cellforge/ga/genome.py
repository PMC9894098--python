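"""Genome and GA hyper-parameter containers.

A genome is a flat float vector: one conductance scaling per roster channel,
then the gap-junction conductance scaling (applied to the 1 nS baseline),
then the coupled-cell count (an integer stored as float).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

SCALING_LOW = 1.0e-4   # 0.01 %
SCALING_HIGH = 10.0    # 1000 %
N_CUSTOM_MIN = 1
N_CUSTOM_MAX = 5
G_GAP_BASELINE_NS = 1.0


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 2500
    generations: int = 5
    crossover_pair_prob: float = 0.9
    crossover_param_prob: float = 0.5
    mutation_prob: float = 0.01
    mutation_sigma_log: float = 0.2
    elite_frac: float = 0.10
    seed: int = 0

    def __post_init__(self):
        for name in ("crossover_pair_prob", "crossover_param_prob",
                     "mutation_prob", "elite_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.population_size < 2 or self.population_size % 2:
            raise ValueError("population size must be even and >= 2")
        if self.generations < 0:
            raise ValueError("generations must be >= 0")


def genome_columns(roster: tuple[str, ...]) -> list[str]:
    return [f"scale_{name}" for name in roster] + ["g_gap_scale", "n_custom"]


def validate_population(pop: np.ndarray, n_channels: int) -> None:
    cont = pop[:, :n_channels + 1]
    if not np.all(cont > 0):
        raise ValueError("all scalings must be > 0")
    ncol = pop[:, n_channels + 1]
    if not np.all((ncol >= N_CUSTOM_MIN) & (ncol <= N_CUSTOM_MAX)
                  & (ncol == np.round(ncol))):
        raise ValueError("n_custom must be an integer in [1, 5]")
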