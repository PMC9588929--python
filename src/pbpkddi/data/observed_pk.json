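{
  "description": "Bundled single-dose verification dataset: clinically observed PK summaries for the five compounds, the reference platform's predicted values (used only to cross-check the fold-error metric), the AUC variant each study reported, and the sampling horizon t_last of the observed study that the simulated AUClast window mirrors.",
  "drugs": {
    "zanubrutinib": {
      "dose_mg": 80.0,
      "auc_variant": "last",
      "t_last_h": 24.0,
      "observed": {"cmax_ng_ml": 162.8, "tmax_h": 1.5, "auc_ng_h_ml": 663.0},
      "reference_predicted": {"cmax_ng_ml": 108.0, "tmax_h": 1.68, "auc_ng_h_ml": 1030.0},
      "reference_fold_error": {"cmax": 1.51, "tmax": 1.12, "auc": 1.55}
    },
    "acalabrutinib": {
      "dose_mg": 100.0,
      "auc_variant": "last",
      "t_last_h": 24.0,
      "observed": {"cmax_ng_ml": 639.0, "tmax_h": 0.5, "auc_ng_h_ml": 643.0},
      "reference_predicted": {"cmax_ng_ml": 390.0, "tmax_h": 0.56, "auc_ng_h_ml": 491.0},
      "reference_fold_error": {"cmax": 1.64, "tmax": 1.12, "auc": 1.31}
    },
    "voriconazole": {
      "dose_mg": 300.0,
      "auc_variant": "last",
      "t_last_h": 12.0,
      "observed": {"cmax_ng_ml": 2360.0, "tmax_h": 1.41, "auc_ng_h_ml": 12650.0},
      "reference_predicted": {"cmax_ng_ml": 2300.0, "tmax_h": 0.99, "auc_ng_h_ml": 21800.0},
      "reference_fold_error": {"cmax": 1.03, "tmax": 1.42, "auc": 1.72}
    },
    "fluconazole": {
      "dose_mg": 100.0,
      "auc_variant": "inf",
      "t_last_h": 96.0,
      "observed": {"cmax_ng_ml": 1700.0, "tmax_h": 4.29, "auc_ng_h_ml": 93000.0},
      "reference_predicted": {"cmax_ng_ml": 1560.0, "tmax_h": 2.49, "auc_ng_h_ml": 75200.0},
      "reference_fold_error": {"cmax": 1.09, "tmax": 1.72, "auc": 1.24}
    },
    "itraconazole": {
      "dose_mg": 200.0,
      "auc_variant": "0-24",
      "t_last_h": 24.0,
      "observed": {"cmax_ng_ml": 280.0, "tmax_h": 4.36, "auc_ng_h_ml": 1970.0},
      "reference_predicted": {"cmax_ng_ml": 201.0, "tmax_h": 3.24, "auc_ng_h_ml": 1930.0},
      "reference_fold_error": {"cmax": 1.39, "tmax": 1.35, "auc": 1.02}
    }
  }
}
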