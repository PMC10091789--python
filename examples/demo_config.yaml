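# Demonstration run: simulate a small cohort, build the analysis table,
# scan rs877087 against heart failure and switching, run TWIST and impact.
out_dir: demo_out
seed: 1
simulate:
  n_patients: 20000
  p_treated: 0.145
  baseline_hazard: 0.002
  beta_treat: 0.0029
  beta_geno: 0.0
  beta_interact: 0.00069
outcomes: [hf, switch]
twist_variant: rs877087
twist_outcome: hf
twist_coding: dominant
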