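import numpy as np
import pytest

from cellforge.metrics import (
    ObjectiveScores, ap_metrics, cat_metrics, normalized_rmse,
)
from conftest import synthetic_waveforms


class TestNormalizedRmse:
    def test_perfect_restoration(self, healthy_ref, untreated_fibrotic_ref):
        s = normalized_rmse(healthy_ref, healthy_ref, untreated_fibrotic_ref)
        assert s.rmse_ap == 0.0 and s.rmse_cat == 0.0
        assert s.accepted

    def test_untreated_scores_exactly_one(self, healthy_ref, untreated_fibrotic_ref):
        s = normalized_rmse(untreated_fibrotic_ref, healthy_ref, untreated_fibrotic_ref)
        assert s.rmse_ap == 1.0
        assert s.rmse_cat == 1.0
        assert not s.accepted

    def test_strict_inequality_at_half(self):
        s = ObjectiveScores(rmse_ap=0.49, rmse_cat=0.50)
        assert s.n_pass == 1
        assert not s.accepted
        assert ObjectiveScores(0.499, 0.499).accepted

    def test_zero_denominator_rejected(self, healthy_ref):
        with pytest.raises(ValueError, match="normalization"):
            normalized_rmse(healthy_ref, healthy_ref, healthy_ref)

    def test_scale_invariance(self, healthy_ref, untreated_fibrotic_ref):
        """Expressing all waveforms in volts leaves normalized RMSE unchanged."""
        from cellforge.coupling import BeatWaveforms
        def volts(wf):
            return BeatWaveforms(ap=wf.ap / 1000.0, cat=wf.cat)
        treated = synthetic_waveforms(
            ap=lambda t: -85.0 + 120.0 * np.exp(-t / 80.0),
            cat=lambda t: 1e-4 + 2e-4 * np.exp(-t / 150.0))
        a = normalized_rmse(treated, healthy_ref, untreated_fibrotic_ref)
        b = normalized_rmse(volts(treated), volts(healthy_ref),
                            volts(untreated_fibrotic_ref))
        assert a.rmse_ap == pytest.approx(b.rmse_ap, rel=1e-12)

    def test_triangle_sanity(self, healthy_ref, untreated_fibrotic_ref):
        treated = synthetic_waveforms(
            ap=lambda t: -80.0 + 100.0 * np.exp(-t / 60.0),
            cat=lambda t: 1e-4 + 1e-4 * np.exp(-t / 100.0))
        h, u = healthy_ref, untreated_fibrotic_ref
        s_t = normalized_rmse(treated, h, u)
        s_u = normalized_rmse(u, h, u)
        # rmse(treated, untreated) on the same normalization
        den = np.sqrt(np.mean((u.ap - h.ap) ** 2))
        tu = np.sqrt(np.mean((treated.ap - u.ap) ** 2)) / den
        assert s_t.rmse_ap <= s_u.rmse_ap + tu + 1e-12


class TestApMetrics:
    def test_trapezoid_closed_form(self):
        """Rest -85, peak +35, plateau to 100 ms then linear repolarization
        to rest at 300 ms: APD50/APD90 from the -25 mV and -73 mV crossings."""
        def trap(t):
            v = np.full_like(t, -85.0)
            up = t <= 2
            v[up] = -85.0 + 60.0 * t[up]          # upstroke 60 mV/ms
            plateau = (t > 2) & (t <= 100)
            v[plateau] = 35.0
            repol = (t > 100) & (t <= 300)
            v[repol] = 35.0 - 120.0 * (t[repol] - 100.0) / 200.0
            return v
        wf = synthetic_waveforms(ap=trap)
        m = ap_metrics(wf)
        assert m.has_ap
        assert m.rmp == -85.0
        assert m.peak_vm == 35.0
        assert m.upstroke_velocity == pytest.approx(60.0)
        # crossing of -25 mV: 100 + 200*(35-(-25))/120 = 200 ms (minus t_up=1)
        assert m.apd50 == pytest.approx(200.0 - 1.0, abs=1.01)
        # crossing of -73 mV: 100 + 200*(35-(-73))/120 = 280 ms
        assert m.apd90 == pytest.approx(280.0 - 1.0, abs=1.01)

    def test_stretch_monotonicity(self):
        """Uniformly stretching repolarization scales APD90 accordingly."""
        def ap(stretch):
            def f(t):
                v = np.full_like(t, -85.0)
                idx = (t >= 1) & (t <= 1 + 200 * stretch)
                v[idx] = 35.0 - 120.0 * (t[idx] - 1) / (200.0 * stretch)
                return v
            return f
        a1 = ap_metrics(synthetic_waveforms(ap=ap(1.0)))
        a2 = ap_metrics(synthetic_waveforms(ap=ap(1.5)))
        assert a2.apd90 == pytest.approx(1.5 * a1.apd90, rel=0.02)

    def test_no_ap_flagged(self):
        wf = synthetic_waveforms(ap=lambda t: -85.0 + 2.0 * np.sin(t / 50.0))
        m = ap_metrics(wf)
        assert not m.has_ap
        assert np.isnan(m.apd90)


class TestCatMetrics:
    def test_exponential_decay_closed_form(self):
        k = 1.0 / 120.0
        wf = synthetic_waveforms(
            cat=lambda t: 1e-4 + np.where(t < 10, 3e-4 * t / 10.0,
                                          3e-4 * np.exp(-k * (t - 10.0))))
        m = cat_metrics(wf)
        assert m.diastolic == pytest.approx(1e-4)
        assert m.peak == pytest.approx(4e-4, rel=1e-3)
        assert m.amplitude == pytest.approx(3e-4, rel=1e-3)
        assert m.tau50 == pytest.approx(np.log(2.0) / k, rel=0.02)
        assert m.tau90 == pytest.approx(np.log(10.0) / k, rel=0.02)

    def test_invariants(self, healthy_ref):
        m = cat_metrics(healthy_ref)
        assert m.amplitude == pytest.approx(m.peak - m.diastolic)
        assert m.amplitude >= 0
        assert np.isnan(m.tau90) or m.tau50 <= m.tau90

    def test_apd_ordering(self, healthy_ref):
        a = ap_metrics(healthy_ref)
        assert a.apd50 <= a.apd90


def test_negative_scores_rejected():
    with pytest.raises(ValueError):
        ObjectiveScores(rmse_ap=-0.1, rmse_cat=0.2)
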