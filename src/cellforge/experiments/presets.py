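"""The named experiment matrix."""

from __future__ import annotations

from dataclasses import dataclass

from ..ga.genome import GAConfig
from ..support_cells.presets import roster as roster_for
from .evaluation import EvalProtocol


@dataclass(frozen=True)
class ExperimentPreset:
    name: str
    phenotype: str                 # cardiomyocyte condition
    roster_name: str               # channel roster preset
    searchable: tuple[str, ...] | None = None  # None = every roster channel
    population: int = 2500
    generations: int = 5

    def __post_init__(self):
        roster = roster_for(self.roster_name)
        for ch in self.searchable or ():
            if ch not in roster:
                raise ValueError(f"searchable parameter {ch!r} not in roster")

    def protocol(self, washin_beats: int, from_rest: bool) -> EvalProtocol:
        return EvalProtocol(phenotype=self.phenotype, washin_beats=washin_beats,
                            from_rest=from_rest, searchable=self.searchable)

    def ga_config(self, seed: int, population: int | None = None,
                  generations: int | None = None) -> GAConfig:
        return GAConfig(population_size=population or self.population,
                        generations=(self.generations if generations is None
                                     else generations),
                        seed=seed)

    def genome_channels(self) -> tuple[str, ...]:
        if self.searchable is None:
            return roster_for(self.roster_name)
        return self.searchable


_FIB = "hf+fibrosis"

EXPERIMENT_PRESETS: dict[str, ExperimentPreset] = {p.name: p for p in [
    ExperimentPreset("nonexcitable-nonfibrotic", "hf", "nonexcitable"),
    ExperimentPreset("nonexcitable-fibrotic", _FIB, "nonexcitable"),
    ExperimentPreset("allchannels-nonfibrotic", "hf", "all-channels"),
    ExperimentPreset("allchannels-fibrotic", _FIB, "all-channels"),
    ExperimentPreset("ical-ik1", _FIB, "ical-ik1"),
    ExperimentPreset("ik1-only", _FIB, "ik1-only"),
    ExperimentPreset("ical-only", _FIB, "ical-only"),
    ExperimentPreset("passive", _FIB, "passive"),
    # engineered-cell translations: only (n, G_gap) and, where present, the
    # cardiomyocyte inward rectifier scaling are searched
    ExperimentPreset("hmsc", _FIB, "hmsc", searchable=()),
    ExperimentPreset("hmsc-ik1", _FIB, "hmsc-ik1", searchable=("hcm_k1",)),
    ExperimentPreset("hcic", _FIB, "hcic", searchable=()),
    ExperimentPreset("hcic-ik1", _FIB, "hcic-ik1", searchable=("hcm_k1",)),
]}


def experiment(name: str) -> ExperimentPreset:
    try:
        return EXPERIMENT_PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown experiment preset {name!r}") from None
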