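{
 "models": [
  {
   "file": "cluster_logistic.json",
   "kind": "logistic",
   "features": [
    "cluster_count",
    "summit_count",
    "std_dev",
    "unencoded_g_frac"
   ],
   "training_data": "packaged synthetic benchmark (n=1000, seed 20250901)",
   "cv_mean_auroc": 0.9677
  }
 ]
}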