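{
  "description": "Reference kinetic constants for the exported alarmone synthetase model. Entries with source 'printed' are the study's fitted constants; entries with source 'representative' are package-chosen values consistent with the printed kcat ratios and the stated Km ranges (guanylate acceptors < 100 uM; adenylate acceptors 20-30x higher), used only to make the full competition design simulable.",
  "km_donor_uM": 82.0,
  "km_donor_source": "printed",
  "enzyme_conc_nM": 0.30,
  "acceptors": {
    "ATP": {"km_uM": 1400.0, "vmax_uM_per_min": 114.0, "source": "printed"},
    "GTP": {"km_uM": 60.0, "vmax_uM_per_min": 110.0, "source": "km representative, vmax printed"},
    "GMP": {"km_uM": 50.0, "vmax_uM_per_min": 148.2, "source": "representative"},
    "ADP": {"km_uM": 1000.0, "vmax_uM_per_min": 136.8, "source": "representative"},
    "AMP": {"km_uM": 1200.0, "vmax_uM_per_min": 216.6, "source": "representative"}
  }
}
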