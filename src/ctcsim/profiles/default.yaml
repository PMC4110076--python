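# Full-scale default profile: two populations of 2000 neurons (80%
# excitatory), small-world recurrent wiring, OU-modulated Poisson drive,
# GABA_A decay setting the gamma rhythm.  Per-edge conductances are given at
# reference_degree and rescaled automatically when mean_degree is reduced.
N: 2000
mean_degree: 100
rewiring_p: 0.3
frac_exc: 0.8
coupling:
  frac_source_exc: 0.9
  frac_target: 0.25
  tau_inter: 0.0
  delay_mode: gamma
  unidirectional: false
  connectivity_ratio: 10.0
ou:
  nu0: 1500.0
  sigma: 100.0
  tau_ou: 16.0
  clip_at_zero: true
  independent: false
stimulus: null
dt: 0.05
duration: 2.0
warmup: 0.2
record_fs: 1000.0
ampa: {tau_r: 0.5, tau_d: 2.0, g_max: 1.0, E_syn: 0.0}
gaba: {tau_r: 0.5, tau_d: 4.0, g_max: 1.0, E_syn: -80.0}
g_exc: 0.03
g_inh: 0.1
g_ext: 0.008
g_inter: 0.015
reference_degree: 100
v_thresh: 0.0
refractory: 2.0
seed: 0
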