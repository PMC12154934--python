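{
  "alpha": 0.05,
  "grand_total": 248,
  "categorical_total": 171,
  "numerical_total": 77,
  "categorical_pct": 53,
  "numerical_pct": 18,
  "by_method_total": {
    "saliency": [27, 14, 41],
    "deconvolution": [25, 8, 33],
    "guided_backprop": [23, 14, 37],
    "input_x_gradient": [9, 8, 17],
    "deeplift": [19, 2, 21],
    "integrated_gradients": [21, 10, 31],
    "lime": [1, 8, 9],
    "kernelshap": [35, 10, 45],
    "gradientshap": [11, 3, 14]
  },
  "by_model_total": {
    "ProtBERT": [56, 22, 78],
    "ProtT5": [50, 34, 84],
    "Ankh": [65, 21, 86]
  },
  "by_method_testtype": {
    "saliency": [20, 21, 21, 20],
    "deconvolution": [17, 16, 16, 17],
    "guided_backprop": [17, 20, 17, 20],
    "input_x_gradient": [7, 10, 7, 10],
    "deeplift": [7, 14, 10, 11],
    "integrated_gradients": [13, 18, 16, 15],
    "lime": [8, 1, 1, 8],
    "kernelshap": [22, 23, 24, 21],
    "gradientshap": [3, 11, 6, 8]
  },
  "by_model_testtype": {
    "target": {"ProtBERT": [23, 13], "ProtT5": [18, 18], "Ankh": [29, 13], "all": [70, 44]},
    "source": {"ProtBERT": [33, 9], "ProtT5": [32, 16], "Ankh": [36, 8], "all": [101, 33]},
    "embedding": {"ProtBERT": [27, 8], "ProtT5": [26, 15], "Ankh": [32, 10], "all": [85, 33]},
    "prediction": {"ProtBERT": [29, 14], "ProtT5": [24, 19], "Ankh": [33, 11], "all": [86, 44]}
  },
  "crosstab_overall": {"pass|pass": 87, "pass|fail": 31, "fail|pass": 43, "fail|fail": 217, "total": 378},
  "crosstab_per_model": {
    "ProtBERT": {"categorical": [21, 6, 8, 19], "numerical": [4, 4, 10, 54]},
    "ProtT5": {"categorical": [22, 4, 2, 26], "numerical": [11, 4, 8, 49]},
    "Ankh": {"categorical": [25, 7, 8, 14], "numerical": [4, 6, 7, 55]}
  },
  "exclusivity": {
    "categorical": {"exactly_one": 24, "at_least_one": 83, "only_Ankh": 14, "pct_of_grid": 22, "pct_of_passed": 29},
    "numerical": {"exactly_one": 37, "at_least_one": 53, "only_ProtT5": 19, "pct_of_passed": 70},
    "all": {"exactly_one": 61, "at_least_one": 136, "pct_of_passed": 45}
  }
}
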