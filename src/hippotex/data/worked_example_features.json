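{
 "seed": 20180529,
 "shape": [
  32,
  32,
  32
 ],
 "center": [
  16,
  16,
  16
 ],
 "roi": "sphere3d_r5",
 "features": {
  "Global Variance": 137.9902383079229,
  "Skewness": 0.18049183317130818,
  "Kurtosis": 2.901776920644488,
  "Energy": 0.0007621938435111654,
  "Contrast": 233.63490251998525,
  "Entropy": 10.724037317282452,
  "Homogeneity": 0.14827907144035066,
  "Correlation": 0.14784065933396767,
  "Sum Average": 61.83793976037416,
  "Variance": 137.08404717912308,
  "Dissimilarity": 12.252253144771146,
  "Autocorrelation": 976.249294371046,
  "SRE": 0.9867136533669895,
  "LRE": 1.0545989239872147,
  "GLN": 12.899173220168127,
  "RLN": 487.4014298635788,
  "RP": 0.9823360161700375,
  "LGRE": 0.004601009016427894,
  "HGRE": 1100.219786227843,
  "SRLGE": 0.004579965874308956,
  "SRHGE": 1086.1231844206195,
  "LRLGE": 0.00468929385239234,
  "LRHGE": 1157.1789588602246,
  "GLV": 138.7203399154135,
  "RLV": 0.018312364241868863
 }
}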