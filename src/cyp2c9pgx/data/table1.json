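{
  "description": "Published CYP2C9 diplotype frequency distributions for five Latin American cohorts and the three Brazilian census race/Color subcohorts. '*1/var' pools *1/*5, *1/*8 and *1/*11.",
  "categories": ["*1/*1", "*1/*2", "*1/*3", "*2/*2", "*2/*3", "*1/var"],
  "cohorts": {
    "Brazilian": {"n": 1057, "frequencies": [0.707, 0.157, 0.082, 0.017, 0.014, 0.021], "kind": "cohort", "census_weighted": true},
    "CLM": {"n": 94, "frequencies": [0.649, 0.223, 0.106, 0.0, 0.021, 0.0], "kind": "cohort"},
    "MXL": {"n": 64, "frequencies": [0.750, 0.203, 0.047, 0.0, 0.0, 0.0], "kind": "cohort"},
    "PEL": {"n": 85, "frequencies": [0.929, 0.047, 0.024, 0.0, 0.0, 0.0], "kind": "cohort"},
    "PUR": {"n": 104, "frequencies": [0.635, 0.229, 0.076, 0.019, 0.010, 0.029], "kind": "cohort"},
    "Black": {"n": 351, "frequencies": [0.812, 0.103, 0.040, 0.003, 0.009, 0.034], "kind": "subcohort"},
    "Brown": {"n": 357, "frequencies": [0.725, 0.132, 0.093, 0.017, 0.008, 0.022], "kind": "subcohort"},
    "White": {"n": 349, "frequencies": [0.670, 0.195, 0.077, 0.020, 0.020, 0.017], "kind": "subcohort"}
  }
}
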