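{
  "comment": "Printed parameter set of the full (t1) Wnt network: fixed priors/CPTs for the non-gene nodes and the gene CPTs from one recorded holdout iteration. Row 0 = state 1 (low/off pole), row 1 = state 2; columns ordered with the first-listed parent varying fastest. MeDKK1/MeDKK4 priors are not printed in the source tables and default to 0.5/0.5. The p1 entries (BETACAT root prior, 2-parent TRCMPLX table) are package defaults mirroring the t1 AND-gate pattern.",
  "fixed": {
    "Sample": {"parents": [], "probs": [[0.5], [0.5]]},
    "TCF4": {"parents": [], "probs": [[0.1], [0.9]]},
    "DVL2": {"parents": ["DACT3"], "probs": [[0.01, 0.99], [0.99, 0.01]]},
    "BETACAT": {"parents": ["DACT1", "DVL2"], "probs": [[0.99, 0.99, 0.99, 0.01], [0.01, 0.01, 0.01, 0.99]]},
    "TRCMPLX": {"parents": ["TCF4", "LEF1", "BETACAT"], "probs": [[0.99, 0.99, 0.99, 0.99, 0.99, 0.99, 0.99, 0.01], [0.01, 0.01, 0.01, 0.01, 0.01, 0.01, 0.01, 0.99]]},
    "MeDACT1": {"parents": [], "probs": [[0.837], [0.163]]},
    "MeDACT2": {"parents": [], "probs": [[0.3376], [0.6624]]},
    "MeWIF1": {"parents": [], "probs": [[0.1667], [0.8333]]},
    "MeSFRP1": {"parents": [], "probs": [[0.6316], [0.3684]]},
    "MeSFRP2": {"parents": [], "probs": [[0.6316], [0.3684]]},
    "MeSFRP4": {"parents": [], "probs": [[0.8572], [0.1428]]},
    "MeSFRP5": {"parents": [], "probs": [[0.75], [0.25]]},
    "MeDKK1": {"parents": [], "probs": [[0.5], [0.5]]},
    "MeDKK4": {"parents": [], "probs": [[0.5], [0.5]]},
    "H3K27me3": {"parents": [], "probs": [[0.2391], [0.7609]]},
    "H3K4me3": {"parents": [], "probs": [[0.3661], [0.6339]]}
  },
  "genes": {
    "LEF1": {"parents": ["Sample"], "probs": [[0.84, 0.16], [0.16, 0.84]]},
    "MYC": {"parents": ["Sample", "TRCMPLX"], "probs": [[0.94, 0.89, 0.78, 0.31], [0.06, 0.11, 0.22, 0.69]]},
    "CCND1": {"parents": ["Sample", "TRCMPLX"], "probs": [[0.95, 0.89, 0.81, 0.28], [0.06, 0.11, 0.18, 0.72]]},
    "CD44": {"parents": ["Sample", "TRCMPLX"], "probs": [[0.93, 0.9, 0.67, 0.42], [0.07, 0.1, 0.33, 0.58]]},
    "DKK1": {"parents": ["Sample", "MeDKK1", "TRCMPLX"], "probs": [[0.95, 0.93, 0.07, 0.05, 0.77, 0.6, 0.4, 0.23], [0.05, 0.07, 0.93, 0.95, 0.23, 0.4, 0.6, 0.76]]},
    "DKK2": {"parents": ["Sample"], "probs": [[0.4, 0.6], [0.6, 0.4]]},
    "DKK3-1": {"parents": ["Sample"], "probs": [[0.36, 0.64], [0.64, 0.36]]},
    "DKK3-2": {"parents": ["Sample"], "probs": [[0.56, 0.44], [0.44, 0.56]]},
    "DKK4": {"parents": ["Sample", "TRCMPLX"], "probs": [[0.94, 0.88, 0.82, 0.28], [0.06, 0.11, 0.18, 0.72]]},
    "DACT1": {"parents": ["Sample", "MeDACT1"], "probs": [[0.56, 0.74, 0.26, 0.44], [0.44, 0.26, 0.74, 0.56]]},
    "DACT2": {"parents": ["Sample", "MeDACT2"], "probs": [[0.6, 0.71, 0.29, 0.4], [0.4, 0.29, 0.71, 0.6]]},
    "DACT3": {"parents": ["H3K27me3", "H3K4me3", "Sample"], "probs": [[0.88, 0.88, 0.12, 0.88, 0.88, 0.88, 0.12, 0.88], [0.12, 0.12, 0.88, 0.12, 0.12, 0.12, 0.88, 0.12]]},
    "SFRP1": {"parents": ["Sample", "MeSFRP1", "TRCMPLX"], "probs": [[0.88, 0.98, 0.02, 0.12, 0.2, 0.96, 0.04, 0.8], [0.12, 0.02, 0.98, 0.88, 0.8, 0.04, 0.96, 0.2]]},
    "SFRP2": {"parents": ["Sample", "MeSFRP2"], "probs": [[0.31, 0.88, 0.11, 0.69], [0.69, 0.11, 0.89, 0.31]]},
    "SFRP3": {"parents": ["Sample"], "probs": [[0.2, 0.8], [0.8, 0.2]]},
    "SFRP4": {"parents": ["Sample", "MeSFRP4"], "probs": [[0.71, 0.6, 0.4, 0.29], [0.29, 0.4, 0.6, 0.71]]},
    "SFRP5": {"parents": ["Sample", "MeSFRP5"], "probs": [[0.31, 0.89, 0.11, 0.69], [0.69, 0.11, 0.89, 0.31]]},
    "WIF1": {"parents": ["Sample", "MeWIF1", "TRCMPLX"], "probs": [[0.96, 0.91, 0.09, 0.04, 0.85, 0.47, 0.56, 0.15], [0.04, 0.09, 0.91, 0.96, 0.15, 0.53, 0.47, 0.85]]}
  },
  "p1_fixed": {
    "BETACAT": {"parents": [], "probs": [[0.5], [0.5]]},
    "TCF4": {"parents": [], "probs": [[0.1], [0.9]]},
    "TRCMPLX": {"parents": ["BETACAT", "TCF4"], "probs": [[0.99, 0.99, 0.99, 0.01], [0.01, 0.01, 0.01, 0.99]]}
  }
}
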