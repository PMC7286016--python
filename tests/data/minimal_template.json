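{
 "cost_functions": [
  {
   "id": "obj_ptv",
   "structure": "ptv",
   "kind": "quadratic_underdose",
   "reference_dose": 67.5,
   "isoconstraint": 0.0,
   "role": "objective"
  },
  {
   "id": "rectum_overdose",
   "structure": "rectum",
   "kind": "quadratic_overdose",
   "reference_dose": 60.0,
   "isoconstraint": 6.0
  }
 ],
 "prescription_items": [
  {
   "id": "ptv_coverage",
   "structure": "ptv",
   "metric": "V_D_at_least",
   "dose_gy": 67.5,
   "threshold": 95.0,
   "direction": "lower_bound"
  },
  {
   "id": "rectum_v60",
   "structure": "rectum",
   "metric": "V_D_at_most",
   "dose_gy": 60.0,
   "threshold": 35.0,
   "direction": "upper_bound"
  }
 ]
}
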