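"""Objective functions (normalized waveform RMSEs with the acceptance rule)
and post-hoc AP / CaT metrics.

Conventions, fixed here because downstream numbers depend on them:
* RMSE is computed pointwise on the shared 1 ms grid over [0, 500] ms of
  the final beat and normalized by the healthy-vs-untreated RMSE.
* Acceptance requires BOTH normalized RMSEs strictly below 0.5.
* tau50/tau90 are threshold-crossing times of the calcium decay (not fitted
  exponential time constants).
* APD is measured from the maximum-upstroke instant, with repolarization
  levels referenced to the amplitude peak - RMP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .coupling.simulate import BeatWaveforms

ACCEPT_THRESHOLD = 0.5


@dataclass(frozen=True)
class ObjectiveScores:
    rmse_ap: float
    rmse_cat: float

    def __post_init__(self):
        if self.rmse_ap < 0 or self.rmse_cat < 0:
            raise ValueError("normalized RMSEs must be >= 0")

    @property
    def n_pass(self) -> int:
        return int(self.rmse_ap < ACCEPT_THRESHOLD) + int(self.rmse_cat < ACCEPT_THRESHOLD)

    @property
    def accepted(self) -> bool:
        return self.n_pass == 2

    @property
    def total(self) -> float:
        """Summed normalized RMSE (selection tie-break key)."""
        return self.rmse_ap + self.rmse_cat


WORST_SCORES = ObjectiveScores(rmse_ap=float("inf"), rmse_cat=float("inf"))


def _rmse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean((np.asarray(a, float) - np.asarray(b, float)) ** 2)))


def normalized_rmse(treated: BeatWaveforms, healthy: BeatWaveforms,
                    untreated: BeatWaveforms) -> ObjectiveScores:
    """Normalized RMSE of the treated waveforms against healthy, scaled by
    the untreated-vs-healthy RMSE."""
    for wf in (treated, healthy, untreated):
        if wf.ap.shape != healthy.ap.shape or wf.cat.shape != healthy.cat.shape:
            raise ValueError("waveform grid mismatch")
    den_ap = _rmse(untreated.ap, healthy.ap)
    den_cat = _rmse(untreated.cat, healthy.cat)
    if den_ap == 0.0 or den_cat == 0.0:
        raise ValueError("untreated and healthy references coincide; "
                         "normalization undefined")
    return ObjectiveScores(rmse_ap=_rmse(treated.ap, healthy.ap) / den_ap,
                           rmse_cat=_rmse(treated.cat, healthy.cat) / den_cat)


@dataclass(frozen=True)
class APMetrics:
    apd50: float            # ms
    apd90: float            # ms
    peak_vm: float          # mV
    upstroke_velocity: float  # mV/ms
    rmp: float              # mV
    has_ap: bool = True


@dataclass(frozen=True)
class CaTMetrics:
    peak: float             # mM
    diastolic: float        # mM
    amplitude: float        # mM
    tau50: float            # ms
    tau90: float            # ms


def _cross_down(t: np.ndarray, x: np.ndarray, start_idx: int, level: float) -> float:
    """First downward crossing time of ``level`` after ``start_idx``
    (linear interpolation); NaN if never crossed."""
    for i in range(start_idx, len(x) - 1):
        if x[i] >= level > x[i + 1]:
            frac = (x[i] - level) / (x[i] - x[i + 1])
            return float(t[i] + frac * (t[i + 1] - t[i]))
    return float("nan")


def ap_metrics(waveform: BeatWaveforms) -> APMetrics:
    vm = waveform.ap
    t = waveform.t
    rmp = float(vm[0])
    peak = float(np.max(vm))
    dvdt = np.diff(vm) / np.diff(t)
    up_idx = int(np.argmax(dvdt))
    vmax = float(np.max(dvdt))
    if peak - rmp < 10.0:
        return APMetrics(apd50=float("nan"), apd90=float("nan"), peak_vm=peak,
                         upstroke_velocity=vmax, rmp=rmp, has_ap=False)
    t_up = float(t[up_idx])
    amp = peak - rmp
    peak_idx = int(np.argmax(vm))
    apd50 = _cross_down(t, vm, peak_idx, peak - 0.5 * amp) - t_up
    apd90 = _cross_down(t, vm, peak_idx, peak - 0.9 * amp) - t_up
    return APMetrics(apd50=apd50, apd90=apd90, peak_vm=peak,
                     upstroke_velocity=vmax, rmp=rmp)


def cat_metrics(waveform: BeatWaveforms) -> CaTMetrics:
    ca = waveform.cat
    t = waveform.t
    diastolic = float(ca[0])
    peak_idx = int(np.argmax(ca))
    peak = float(ca[peak_idx])
    amp = peak - diastolic
    tau50 = _cross_down(t, ca, peak_idx, peak - 0.5 * amp) - t[peak_idx]
    tau90 = _cross_down(t, ca, peak_idx, peak - 0.9 * amp) - t[peak_idx]
    return CaTMetrics(peak=peak, diastolic=diastolic, amplitude=amp,
                      tau50=float(tau50), tau90=float(tau90))
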