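{
 "variant": "B",
 "note": "Fixture ground truth for the neck-swinging (negative-feedback) variant. Shares the turnover scales of variant A; the PKD-dependent phosphorylation of free CERT (k_phos_free) plus an unsaturated PKDpDAG->CERT phosphorylation and a less regulator-sensitive recruitment path make the net PKD->transfer coupling negative (raising basal PKD activation lowers steady-state transfer).",
 "parameters": {
  "vmax1": 1.2e6, "K1E": 2e4, "K1S": 1e7,
  "kdp_PI4K": 0.5,
  "vmax3": 5e5, "K3E": 1e5, "K3S": 1e6,
  "k9": 2.0,
  "vmax5": 1e6, "K5E": 2e5, "K5S": 1e6,
  "k10": 1.0,
  "k_act": 0.05, "vmax_cer": 6e4, "K_cer": 3e6,
  "k_pdbu": 2.0, "k_deact": 1.0, "k_inh": 20.0,
  "s_PKD": 2.5e4, "s_PI4K": 1e5, "s_CERT": 2.5e4,
  "s_ect_PI4K": 2e6, "s_ect_CERT": 2e6,
  "d_PKD": 0.05, "d_PI4K": 0.05, "d_CERT": 0.05,
  "k_phos_free": 1e-5
 }
}
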