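# Desk-scale demonstration: simulate a mutator population with rare sweeps,
# recover clusters/lineages from the noisy trajectory table, fit the clock,
# and estimate model parameters from the experiment's fixation counts.
simulate:
  popsize: 1000
  mu: 2.0e-5          # per bp per generation (desk-scale inflated)
  ls: 300             # synonymous sites
  ln: 700             # non-synonymous sites
  alpha: 0.001        # adaptive fraction of non-synonymous mutations
  beta: 0.4           # harmful fraction of non-synonymous mutations
  s_adaptive: 0.08
  s_harmful: -0.02
  generations: 6000
  sample_every: 400
  obs_sd: 0.062       # Sanger peak-ratio noise
clustering:
  tolerance: 0.124    # two Sanger standard deviations
clock:
  baseline_generation: 0
  synonymous_sites: 300
  nonsynonymous_sites: 700
  mu: 2.0e-5
estimate:
  syn_fixed: 32
  nonsyn_fixed: 62
  n_hitchhikes: 20
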