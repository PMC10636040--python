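{
 "format": "captss-logistic",
 "version": "1",
 "feature_names": [
  "cluster_count",
  "summit_count",
  "std_dev",
  "unencoded_g_frac"
 ],
 "scaler_mean": [
  1799.3075669909824,
  177.03626384784795,
  24.116068267410483,
  0.4308118000610107
 ],
 "scaler_scale": [
  1345.975183975252,
  264.7076588992599,
  15.842077344840243,
  0.2017871712254692
 ],
 "coef": [
  -0.37184960524478156,
  2.823637929616047,
  -2.1306918563561683,
  1.8111728355712238
 ],
 "intercept": -0.04968338577274817
}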