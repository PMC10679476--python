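{
 "schema_version": 1,
 "name": "ehr_random_intercept",
 "version": "2023",
 "strata": {
  "M:sbp": {
   "fixed": {
    "intercept": "103.88965",
    "age1": "1.71846",
    "age2": "0.11811",
    "age3": "-0.00064",
    "age4": "-0.00144",
    "height1": "1.25749",
    "height3": "-0.02279",
    "height4": "0.01146"
   },
   "sigma": "9.644",
   "metadata": {"icc": "0.34", "r2_train": "0.399", "r2_test": "0.401", "n_children": 137598}
  },
  "F:sbp": {
   "fixed": {
    "intercept": "104.04188",
    "age1": "1.65051",
    "age2": "-0.00118",
    "age3": "-0.00691",
    "age4": "-0.00031",
    "height1": "0.98468",
    "height2": "0.06251",
    "height4": "0.00694"
   },
   "sigma": "9.514",
   "metadata": {"icc": "0.34", "r2_train": "0.316", "r2_test": "0.318", "n_children": 154814}
  },
  "M:dbp": {
   "fixed": {
    "intercept": "62.26646",
    "age1": "0.74699",
    "age2": "-0.01614",
    "age3": "-0.00146",
    "age4": "0.00042",
    "height1": "0.36553"
   },
   "sigma": "7.312",
   "metadata": {"icc": "0.27", "r2_train": "0.137", "r2_test": "0.133", "n_children": 137598}
  },
  "F:dbp": {
   "fixed": {
    "intercept": "62.46709",
    "age1": "0.79915",
    "age2": "-0.00742",
    "age3": "-0.00249",
    "age4": "0.00014",
    "height1": "0.38153"
   },
   "sigma": "7.261",
   "metadata": {"icc": "0.28", "r2_train": "0.141", "r2_test": "0.140", "n_children": 154814}
  }
 }
}
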