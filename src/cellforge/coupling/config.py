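"""Coupling configuration for the heterocellular simulation."""

from __future__ import annotations

from dataclasses import dataclass

PHENOTYPES = ("healthy", "hf", "hf+fibrosis")


@dataclass(frozen=True)
class CouplingConfig:
    """One cardiomyocyte, optional fibroblasts, optional custom cells.

    Paper-replication settings: 1 Hz pacing, 500 beats, and for the fibrotic
    condition 5 fibroblasts at 1 nS each.
    """

    phenotype: str = "hf+fibrosis"
    n_fibroblasts: int | None = None   # default: 5 iff fibrotic, else 0
    g_fib_gap: float = 1.0             # nS
    n_custom: int = 0                  # 0 = no custom cell attached
    g_gap: float = 1.0                 # nS, custom cell <-> cardiomyocyte
    pacing_hz: float = 1.0
    n_beats: int = 500
    record_beats: int = 1
    stim_amp: float = -80.0            # uA/uF
    stim_dur: float = 0.5              # ms

    def __post_init__(self):
        if self.phenotype not in PHENOTYPES:
            raise ValueError(f"unknown phenotype {self.phenotype!r}")
        if self.n_fibroblasts is None:
            object.__setattr__(
                self, "n_fibroblasts", 5 if self.phenotype == "hf+fibrosis" else 0)
        if self.n_fibroblasts < 0:
            raise ValueError("n_fibroblasts must be >= 0")
        if self.n_custom < 0:
            raise ValueError("n_custom must be >= 0")
        if self.g_gap < 0 or self.g_fib_gap < 0:
            raise ValueError("gap conductances must be >= 0")
        if self.pacing_hz <= 0 or self.n_beats < 1:
            raise ValueError("pacing_hz must be > 0 and n_beats >= 1")
        if self.record_beats < 0 or self.record_beats > self.n_beats:
            raise ValueError("record_beats must be in [0, n_beats]")

    @property
    def cycle_length_ms(self) -> float:
        return 1000.0 / self.pacing_hz
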