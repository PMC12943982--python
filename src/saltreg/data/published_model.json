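{
  "terms": ["X2", "X4", "X1^2", "X2^2", "X4^2"],
  "slopes": [4.874e-2, 1.261e-2, -3.803e-4, -5.280e-4, -3.009e-5],
  "cov": [
    [2.411e-5, -5.088e-6, -3.172e-7, -2.381e-7, 1.764e-8],
    [-5.088e-6, 2.135e-6, 1.585e-8, 5.244e-8, -8.001e-9],
    [-3.172e-7, 1.585e-8, 8.942e-9, 2.227e-9, -1.135e-11],
    [-2.381e-7, 5.244e-8, 2.227e-9, 2.908e-9, -2.118e-10],
    [1.764e-8, -8.001e-9, -1.135e-11, -2.118e-10, 3.380e-11]
  ],
  "reported_slope_sds": [4.91e-3, 1.46e-3, 9.46e-5, 5.39e-5, 5.81e-6],
  "reported_correlations": {
    "(2,1)": -0.7091,
    "(3,1)": -0.6832,
    "(3,2)": 0.1147,
    "(4,1)": -0.8992,
    "(4,2)": 0.6655,
    "(4,3)": 0.4368,
    "(5,1)": 0.6180,
    "(5,2)": -0.9419,
    "(5,3)": -0.02065,
    "(5,4)": -0.6757
  },
  "resid_sd": 0.280,
  "dof": 119,
  "provenance": "published: reported final slopes, HC3 covariance and residual SD (124 records, 5 terms)"
}
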