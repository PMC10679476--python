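{
 "schema_version": 1,
 "name": "ehr_random_slopes",
 "version": "2023",
 "strata": {
  "M:sbp": {
   "fixed": {
    "intercept": "103.81317",
    "age1": "1.73361",
    "age2": "0.12287",
    "age3": "-0.00068",
    "age4": "-0.00149",
    "height1": "1.24648",
    "height3": "-0.02799",
    "height4": "0.01454"
   },
   "random_effects": {
    "sigma_intercept": "5.03383",
    "sigma_age": "0.53342",
    "sigma_height": "1.21332",
    "rho_intercept_age": "0.34877",
    "rho_intercept_height": "-0.0007",
    "rho_age_height": "0.12559",
    "sigma_observation": "7.76685"
   },
   "metadata": {"r2_train": "0.399", "r2_test": "0.401", "n_children": 137598}
  },
  "F:sbp": {
   "fixed": {
    "intercept": "103.97061",
    "age1": "1.64756",
    "age3": "-0.00673",
    "age4": "-0.00030",
    "height1": "0.98278",
    "height2": "0.07001",
    "height4": "0.00720"
   },
   "random_effects": {
    "sigma_intercept": "5.02626",
    "sigma_age": "0.49579",
    "sigma_height": "1.00908",
    "rho_intercept_age": "0.3473",
    "rho_intercept_height": "-0.04389",
    "rho_age_height": "-0.00832",
    "sigma_observation": "7.65618"
   },
   "metadata": {"r2_train": "0.316", "r2_test": "0.318", "n_children": 154814}
  },
  "M:dbp": {
   "fixed": {
    "intercept": "62.22508",
    "age1": "0.67985",
    "age2": "-0.01321",
    "age3": "-0.00033",
    "age4": "0.00039",
    "height1": "0.36050",
    "height4": "0.00410"
   },
   "random_effects": {
    "sigma_intercept": "3.28489",
    "sigma_age": "0.4688",
    "sigma_height": "0.77311",
    "rho_intercept_age": "0.20928",
    "rho_intercept_height": "-0.05694",
    "rho_age_height": "0.08343",
    "sigma_observation": "6.12374"
   },
   "metadata": {"r2_train": "0.137", "r2_test": "0.133", "n_children": 137598}
  },
  "F:dbp": {
   "fixed": {
    "intercept": "62.41751",
    "age1": "0.72471",
    "age2": "-0.00411",
    "age3": "-0.00126",
    "age4": "0.00010",
    "height1": "0.37092"
   },
   "random_effects": {
    "sigma_intercept": "3.34873",
    "sigma_age": "0.45282",
    "sigma_height": "0.80022",
    "rho_intercept_age": "0.22796",
    "rho_intercept_height": "-0.07968",
    "rho_age_height": "0.09753",
    "sigma_observation": "6.04074"
   },
   "metadata": {"r2_train": "0.141", "r2_test": "0.140", "n_children": 154814}
  }
 }
}
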