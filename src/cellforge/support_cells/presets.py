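"""Named channel-roster presets for the in-paper experiment matrix."""

from __future__ import annotations

from .custom_cell import CustomCellSpec

_NONEXCITABLE = (
    "hcic_na", "hcic_kir", "hcic_bk", "hcic_to",
    "hmsc_to", "hmsc_to_ss", "hmsc_na", "hmsc_cal", "hmsc_kca", "hmsc_dr",
    "cf_kv", "cf_kir", "cf_nak",
)
_HCM = ("hcm_na", "hcm_nal", "hcm_to", "hcm_cal", "hcm_kr", "hcm_ks", "hcm_k1")
_HMSC = ("hmsc_to", "hmsc_to_ss", "hmsc_na", "hmsc_cal", "hmsc_kca", "hmsc_dr")
_HCIC = ("hcic_na", "hcic_kir", "hcic_bk", "hcic_to")

ROSTER_PRESETS: dict[str, tuple[str, ...]] = {
    "nonexcitable": _NONEXCITABLE,
    "all-channels": _NONEXCITABLE + _HCM,
    "ical-ik1": ("hcm_cal", "hcm_k1"),
    "ik1-only": ("hcm_k1",),
    "ical-only": ("hcm_cal",),
    "passive": ("passive_leak",),
    "hmsc": _HMSC,
    "hmsc-ik1": _HMSC + ("hcm_k1",),
    "hcic": _HCIC,
    "hcic-ik1": _HCIC + ("hcm_k1",),
}


def roster(name: str) -> tuple[str, ...]:
    try:
        return ROSTER_PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown roster preset {name!r}") from None


def spec_for(name: str, scalings=None) -> CustomCellSpec:
    r = roster(name)
    if scalings is None:
        return CustomCellSpec(roster=r)
    return CustomCellSpec(roster=r, scalings=tuple(scalings))
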