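{
  "rmsd_column": "RMSD",
  "columns": {
    "RMSD": {"direction": null, "units": "angstrom"},
    "prime_gfactor": {"direction": "positive_better", "units": "au"},
    "prime_energy": {"direction": "negative_better", "units": "kcal/mol"},
    "yasara_zscore": {"direction": "positive_better", "units": "au"},
    "yasara_energy": {"direction": "negative_better", "units": "kcal/mol"},
    "dope": {"direction": "negative_better", "units": "au"}
  }
}
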