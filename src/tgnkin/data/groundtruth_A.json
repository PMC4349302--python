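{
 "variant": "A",
 "note": "Fixture ground truth for the shuttle (positive-feedback) variant. Endogenous totals near the measured magnitudes (PI4KIIIb ~2e6, PKD ~5e5, CERT ~5e5 molecules/cell), mostly unphosphorylated PKD/PI4KIIIb at rest. The PKDpDAG->CERT phosphorylation is regulator-saturated (small K3E) while PI4KIIIb activation is not, so raising PKD activity increases net transfer (positive coupling, ~+5% transfer for +10% active PKD). The transfer-dependent activation channel is sized so ectopic-expression responses are visible above blot noise, which makes the synthetic study design informative about the feedback structure.",
 "parameters": {
  "vmax1": 3.6e6, "K1E": 2e5, "K1S": 1e7,
  "kdp_PI4K": 0.5,
  "vmax3": 6e5, "K3E": 5e3, "K3S": 1e6,
  "k9": 4.0,
  "vmax5": 3e6, "K5E": 1e6, "K5S": 1e6,
  "k10": 1.0,
  "k_act": 0.05, "vmax_cer": 8e4, "K_cer": 3e6,
  "k_pdbu": 2.0, "k_deact": 1.0, "k_inh": 20.0,
  "s_PKD": 2.5e4, "s_PI4K": 1e5, "s_CERT": 2.5e4,
  "s_ect_PI4K": 2e6, "s_ect_CERT": 2e6,
  "d_PKD": 0.05, "d_PI4K": 0.05, "d_CERT": 0.05
 }
}
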