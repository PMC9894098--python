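"""Maximal conductance/permeability parameter sets for the human endocardial
ventricular cardiomyocyte, with the heart-failure (reduced ejection fraction)
remodeling applied as documented multiplicative factors.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict, fields
from pathlib import Path

import yaml

from ..constants import CM_CAPACITANCE_PF

_DATA_DIR = Path(__file__).resolve().parent.parent / "data"


@dataclass(frozen=True)
class CMParameters:
    """Maximal conductances (mS/uF), permeabilities (cm/s scaled), pump and
    flux magnitudes of the endocardial ventricular cell, plus capacitance and
    phenotype tag.
    """

    g_na: float = 14.838        # fast Na+, ten Tusscher formulation
    g_nal: float = 0.0075       # late Na+
    g_to: float = 0.02          # transient outward K+
    p_cal: float = 0.0001       # L-type Ca2+ permeability
    g_kr: float = 0.046         # rapid delayed rectifier K+
    g_ks: float = 0.0034        # slow delayed rectifier K+
    g_k1: float = 0.1908        # inward rectifier K+
    g_ncx: float = 0.0008       # Na+/Ca2+ exchanger magnitude
    p_nak: float = 30.0         # Na+/K+ pump magnitude
    g_kb: float = 0.003         # background K+
    p_nab: float = 3.75e-10     # background Na+
    p_cab: float = 2.5e-8       # background Ca2+
    g_pca: float = 0.0005       # sarcolemmal Ca2+ pump
    jup_scale: float = 1.0      # SERCA uptake scale
    jleak_scale: float = 1.0    # SR leak scale
    jrel_scale: float = 1.0     # RyR release scale
    camk_o: float = 0.05        # CaMK fraction (bound+active at saturation)
    hl_tau_scale: float = 1.0   # late Na+ inactivation time-constant scale
    c_cm: float = CM_CAPACITANCE_PF  # pF
    phenotype: str = "healthy"

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "phenotype":
                continue
            v = getattr(self, f.name)
            if not (v >= 0.0):
                raise ValueError(f"parameter {f.name} must be >= 0, got {v}")
        if self.c_cm <= 0.0:
            raise ValueError("c_cm must be > 0")
        if self.phenotype not in ("healthy", "hf"):
            raise ValueError(f"unknown phenotype {self.phenotype!r}")

    def to_dict(self) -> dict:
        return asdict(self)


# Multiplicative ionic remodeling of HF with reduced ejection fraction,
# relative to the healthy endocardial cell.
HF_REMODELING_FACTORS: dict[str, float] = {
    "g_nal": 1.80,      # late Na+ up-regulated
    "g_to": 0.40,       # transient outward down-regulated
    "g_k1": 0.68,       # inward rectifier down-regulated
    "g_ncx": 1.75,      # exchanger up-regulated
    "p_nak": 0.70,      # pump down-regulated
    "jup_scale": 0.45,  # SERCA uptake reduced
    "jleak_scale": 1.30,  # SR leak increased
    "camk_o": 1.50,     # CaMK activity increased
}


def healthy_parameters() -> CMParameters:
    """The published healthy endocardial parameter set."""
    return CMParameters()


def apply_hf_remodeling(params: CMParameters) -> CMParameters:
    """Return a new parameter set with the HF remodeling factors applied.

    Raises ``ValueError`` if the input is already remodeled (idempotence
    guard); all untouched parameters are bit-identical to the input.
    """
    if params.phenotype != "healthy":
        raise ValueError("HF remodeling may only be applied to a healthy parameter set")
    scaled = {k: getattr(params, k) * f for k, f in HF_REMODELING_FACTORS.items()}
    return replace(params, phenotype="hf", **scaled)


def parameters_for(phenotype: str) -> CMParameters:
    if phenotype == "healthy":
        return healthy_parameters()
    if phenotype in ("hf", "hf+fibrosis"):
        return apply_hf_remodeling(healthy_parameters())
    raise ValueError(f"unknown phenotype {phenotype!r}")


def load_parameters(path: str | Path) -> CMParameters:
    """Load a parameter set from a YAML file (units as in CMParameters)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return CMParameters(**raw)


def dump_parameters(params: CMParameters, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


def shipped_parameters(phenotype: str) -> CMParameters:
    """Load the versioned plain-text parameter file shipped with the package."""
    name = "cm_healthy.yaml" if phenotype == "healthy" else "cm_hf.yaml"
    return load_parameters(_DATA_DIR / name)
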