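import numpy as np
import pytest

from cellforge import layout as L
from cellforge.constants import CM_CAPACITANCE_PF, CUSTOM_CAPACITANCE_PF
from cellforge.coupling import (
    BeatWaveforms, CouplingConfig, Trace, extract_final_beat, simulate,
)
from cellforge.support_cells.presets import roster, spec_for


def capacitor_spec():
    r = roster("all-channels")
    return spec_for("all-channels", [0.0] * len(r))


class TestConfig:
    def test_fibrotic_defaults_five_fibroblasts(self):
        cfg = CouplingConfig(phenotype="hf+fibrosis")
        assert cfg.n_fibroblasts == 5
        assert cfg.g_fib_gap == 1.0

    def test_nonfibrotic_default_no_fibroblasts(self):
        assert CouplingConfig(phenotype="hf").n_fibroblasts == 0

    def test_invalid(self):
        with pytest.raises(ValueError):
            CouplingConfig(phenotype="dog")
        with pytest.raises(ValueError):
            CouplingConfig(g_gap=-1.0)
        with pytest.raises(ValueError):
            CouplingConfig(n_beats=0)

    def test_spec_required_iff_custom(self):
        with pytest.raises(ValueError, match="spec"):
            simulate(CouplingConfig(phenotype="healthy", n_custom=1, n_beats=1))
        with pytest.raises(ValueError, match="n_custom"):
            simulate(CouplingConfig(phenotype="healthy", n_custom=0, n_beats=1),
                     capacitor_spec())


def test_zero_gap_decouples(healthy_prepaced):
    base = simulate(CouplingConfig(phenotype="healthy", n_beats=2, record_beats=1),
                    y0=healthy_prepaced)
    coupled = simulate(CouplingConfig(phenotype="healthy", n_custom=3, g_gap=0.0,
                                      n_beats=2, record_beats=1),
                       capacitor_spec(), y0=healthy_prepaced)
    np.testing.assert_array_equal(base.vm_cm, coupled.vm_cm)
    np.testing.assert_array_equal(base.cai, coupled.cai)


def test_rc_pair_closed_form():
    """Capacitor cardiomyocyte + capacitor custom cell: exponential
    convergence at the analytic rate and conservation of total charge."""
    from dataclasses import replace
    from cellforge.cardiomyocyte.parameters import healthy_parameters
    zeroed = {f: 0.0 for f in ("g_na", "g_nal", "g_to", "p_cal", "g_kr", "g_ks",
                               "g_k1", "g_ncx", "p_nak", "g_kb", "p_nab",
                               "p_cab", "g_pca")}
    params = replace(healthy_parameters(), **zeroed)
    g = 2.0  # nS
    cfg = CouplingConfig(phenotype="healthy", n_custom=1, g_gap=g,
                         n_beats=1, record_beats=1, stim_amp=0.0)
    tr = simulate(cfg, capacitor_spec(), cm_params=params)
    c1, c2 = CM_CAPACITANCE_PF, CUSTOM_CAPACITANCE_PF
    v1_0, v2_0 = tr.vm_cm[0], tr.vm_custom[0]
    # analytic solution of the linear pair
    k = g * (1.0 / c1 + 1.0 / c2)  # 1/ms
    vbar = (c1 * v1_0 + c2 * v2_0) / (c1 + c2)
    t = tr.t
    v1_exact = vbar + (v1_0 - vbar) * np.exp(-k * t)
    v2_exact = vbar + (v2_0 - vbar) * np.exp(-k * t)
    np.testing.assert_allclose(tr.vm_cm, v1_exact, atol=5e-3)
    np.testing.assert_allclose(tr.vm_custom, v2_exact, atol=5e-3)
    charge = c1 * tr.vm_cm + c2 * tr.vm_custom
    np.testing.assert_allclose(charge, charge[0], rtol=1e-9)


def test_custom_capacitor_tracks_lowpass_ap(healthy_prepaced):
    """All-scalings-zero custom cell follows a low-pass-filtered AP; verified
    against an exact-exponential two-compartment oracle driven by the
    recorded cardiomyocyte voltage."""
    g, c2 = 1.0, CUSTOM_CAPACITANCE_PF
    cfg = CouplingConfig(phenotype="healthy", n_custom=1, g_gap=g,
                         n_beats=3, record_beats=2)
    tr = simulate(cfg, capacitor_spec(), y0=healthy_prepaced)
    # brute-force RC oracle on the 1 ms grid
    tau = c2 / g
    vc = np.empty_like(tr.vm_custom)
    vc[0] = tr.vm_custom[0]
    a = np.exp(-1.0 / tau)
    for i in range(1, len(vc)):
        drive = 0.5 * (tr.vm_cm[i - 1] + tr.vm_cm[i])
        vc[i] = drive + (vc[i - 1] - drive) * a
    err = np.abs(vc - tr.vm_custom)
    assert err.max() < 1.5  # mV; grid-level oracle tolerance


def test_gap_current_antisymmetry(fibrotic_prepaced):
    cfg = CouplingConfig(phenotype="hf+fibrosis", n_custom=4, g_gap=3.0,
                         n_beats=2, record_beats=1)
    tr = simulate(cfg, spec_for("ik1-only", [2.0]), y0=fibrotic_prepaced)
    total = tr.currents["Igap_custom"]
    one = tr.currents["Igap_custom_one"]
    np.testing.assert_allclose(total, 4.0 * one, rtol=1e-12)


def test_peak_gap_current_monotone_in_ggap(fibrotic_prepaced):
    peaks = []
    for g in (0.5, 2.0, 8.0):
        cfg = CouplingConfig(phenotype="hf+fibrosis", n_custom=2, g_gap=g,
                             n_beats=3, record_beats=1)
        tr = simulate(cfg, spec_for("ik1-only", [2.0]), y0=fibrotic_prepaced)
        peaks.append(np.max(np.abs(tr.currents["Igap_custom"])))
    assert peaks[0] < peaks[1] < peaks[2]


def test_determinism(fibrotic_prepaced):
    cfg = CouplingConfig(phenotype="hf+fibrosis", n_custom=2, g_gap=3.0,
                         n_beats=2, record_beats=1)
    a = simulate(cfg, spec_for("ical-ik1", [1.0, 2.0]), y0=fibrotic_prepaced)
    b = simulate(cfg, spec_for("ical-ik1", [1.0, 2.0]), y0=fibrotic_prepaced)
    np.testing.assert_array_equal(a.vm_cm, b.vm_cm)
    np.testing.assert_array_equal(a.cai, b.cai)


def test_initial_custom_vm_washes_out(fibrotic_prepaced):
    from cellforge.metrics import normalized_rmse
    from cellforge.experiments.references import reference_waveforms
    wfs = []
    for vm0 in (-80.0, -20.0):
        y0 = fibrotic_prepaced.copy()
        y0[L.CU_V] = vm0
        cfg = CouplingConfig(phenotype="hf+fibrosis", n_custom=3, g_gap=5.0,
                             n_beats=30, record_beats=1)
        tr = simulate(cfg, spec_for("ik1-only", [3.0]), y0=y0)
        wfs.append(extract_final_beat(tr))
    h = reference_waveforms("healthy")
    u = reference_waveforms("hf+fibrosis")
    s0 = normalized_rmse(wfs[0], h, u)
    s1 = normalized_rmse(wfs[1], h, u)
    assert abs(s0.rmse_ap - s1.rmse_ap) < 1e-3
    assert abs(s0.rmse_cat - s1.rmse_cat) < 1e-3


class TestExtractFinalBeat:
    def test_window_arithmetic(self):
        t = np.arange(2001, dtype=float)
        vm = np.sin(2 * np.pi * t / 400.0)
        ca = 1e-4 + 5e-5 * np.cos(2 * np.pi * t / 400.0)
        tr = Trace(t=t, vm_cm=vm, vm_fib=np.zeros_like(t), vm_custom=np.zeros_like(t),
                   cai=ca, cycle_length_ms=1000.0)
        wf = extract_final_beat(tr)
        np.testing.assert_array_equal(wf.ap, vm[1000:1501])
        np.testing.assert_array_equal(wf.cat, ca[1000:1501])

    def test_too_short_rejected(self):
        t = np.arange(300, dtype=float)
        z = np.zeros_like(t)
        tr = Trace(t=t, vm_cm=z, vm_fib=z, vm_custom=z, cai=z + 1e-4)
        with pytest.raises(ValueError, match="window|cycle"):
            extract_final_beat(tr)

    def test_healthy_final_beat_sane(self, healthy_ref):
        assert healthy_ref.ap.max() - healthy_ref.ap.min() > 90.0
        assert healthy_ref.cat.max() > healthy_ref.cat[0]


def test_waveform_shape_enforced():
    with pytest.raises(ValueError, match="501"):
        BeatWaveforms(ap=np.zeros(400), cat=np.zeros(400))
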