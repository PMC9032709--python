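{
  "dose_mg": 50.0,
  "blood_volume_ml": 12.78,
  "table1": {
    "file": "table1.csv",
    "source": "in vivo rat study: 50 mg sulfathiazole suspension administered orally, with and without added tenside (sucrose monolaurate); seven samples over 0-6 h; concentrations converted to amounts via the rat blood volume",
    "note": "the t = 4 h concentration/amount pair is internally inconsistent: every other pair shares the amount/concentration ratio 12.78 mL, while 0.952/0.0735 = 12.95 mL; both printed values are shipped verbatim"
  },
  "params": {
    "two_compartment_no_tenside": {"ka": 0.030272, "ke1": 0.649656, "ke2": 0.338477},
    "two_compartment_tenside": {"ka": 0.045815, "ke1": 0.959041, "ke2": 0.242913},
    "three_compartment_no_tenside": {"ka": 0.0370, "ke1": 0.1214, "k23": 1.2725, "ke3": 0.2171},
    "three_compartment_tenside": {"ka": 0.0438, "ke1": 0.9634, "k23": 0.2115, "ke3": 0.2438}
  },
  "params_note": "rate constants (1/h) identified from the no-tenside/tenside sample rows; the two-compartment sets observe the central compartment, the three-compartment sets observe the tissue compartment",
  "matrices": {
    "matrix_two_compartment_no_tenside": {
      "A": [[-0.6799, 0.0], [0.0303, -0.3385]]
    },
    "interval_two_compartment_no_tenside_delta10": {
      "A_hi": [[-0.6119, 0.0], [0.0333, -0.3046]],
      "A_lo": [[-0.7479, 0.0], [0.0272, -0.3723]],
      "c_hi": [0.0, 1.1],
      "c_lo": [0.0, 0.9],
      "note": "the (1,1) entry of A_lo was printed with a shifted decimal point (-7.4790) in the source; the corrected -0.7479, consistent with the +/-10% rule and with the published 0.9-1.38 mg envelope range, is shipped"
    },
    "matrix_three_compartment_no_tenside": {
      "A": [[-0.1584, 0.0, 0.0], [0.0370, -1.2725, 0.0], [0.0, 1.2725, -0.2171]]
    },
    "interval_three_compartment_no_tenside_delta10": {
      "A_hi": [[-0.1426, 0.0, 0.0], [0.0407, -1.1452, 0.0], [0.0, 1.3998, -0.1954]],
      "A_lo": [[-0.1742, 0.0, 0.0], [0.0333, -1.3998, 0.0], [0.0, 1.1452, -0.2388]]
    },
    "matrix_three_compartment_tenside": {
      "A": [[-1.0072, 0.0, 0.0], [0.0438, -0.2115, 0.0], [0.0, 0.2115, -0.2438]]
    },
    "interval_three_compartment_tenside_delta10": {
      "A_hi": [[-0.9065, 0.0, 0.0], [0.0482, -0.1903, 0.0], [0.0, 0.2326, -0.2194]],
      "A_lo": [[-1.1079, 0.0, 0.0], [0.0394, -0.2326, 0.0], [0.0, 0.1903, -0.2682]]
    }
  }
}
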