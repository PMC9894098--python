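g_na: 14.838
g_nal: 0.0135
g_to: 0.008
p_cal: 0.0001
g_kr: 0.046
g_ks: 0.0034
g_k1: 0.129744
g_ncx: 0.0014
p_nak: 21.0
g_kb: 0.003
p_nab: 3.75e-10
p_cab: 2.5e-08
g_pca: 0.0005
jup_scale: 0.45
jleak_scale: 1.3
jrel_scale: 1.0
camk_o: 0.07500000000000001
hl_tau_scale: 1.0
c_cm: 153.35760000000002
phenotype: hf
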