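# Simulation presets for virtual skin-segment cohorts.
#
# Values are cohort summaries observed on real fruit (modulus in MPa,
# strains dimensionless, pressures kPa); the simulator draws per-specimen
# parameters from these distributions.  Mechanical noise levels and the
# protocol parameters are package defaults, not measurements.

defaults: &defaults
  E_inst: 23.2              # MPa, instantaneous (apparent) modulus
  E_cv: 0.0                 # per-specimen CV of E (0 = deterministic)
  creep_m: 0.0              # hold strain per ln(s) at the 10 kPa reference hold
  creep_t0: 1.0             # s, log-kernel regularisation time
  plastic_fraction: 0.0     # fraction of elastic strain accrued irreversibly
  eps_fracture_mean: 0.20   # area strain at fracture
  eps_fracture_cv: 0.0
  edge_failure_prob: 0.2    # fraction fracturing at the orifice edge
  nu: 0.74                  # Poisson's ratio
  in_vivo_release_strain: 0.155
  center_amplification_g: 2.16   # centre-dot vs mean strain factor
  pressure_ramp_rate: 0.25  # kPa/s
  sampling_dt: 1.0          # s
  noise_sd_height: 0.0      # mm
  noise_sd_pressure: 0.0    # kPa
  noise_sd_marker: 0.0      # mm
  orifice_D: 12.0           # mm
  thickness_t: 0.1          # mm, load-bearing layer
  uniaxial_strain_rate: 0.00278   # 1/s (3 mm/min on an 18 mm gauge)
  uniaxial_stiffness: 10.0  # N per unit axial strain
  seed: 0

# Sweet cherry, pooled control cohorts
sweet_cherry_2012:
  <<: *defaults
  E_inst: 23.2
  E_cv: 0.25
  eps_fracture_mean: 0.20
  eps_fracture_cv: 0.18
  n: 84

sweet_cherry_2013:
  <<: *defaults
  E_inst: 25.2
  E_cv: 0.40
  eps_fracture_mean: 0.21
  eps_fracture_cv: 0.29
  n: 115

# In-vivo strain maintained vs released contrast (10 replicates per arm,
# read as post-exclusion counts; fracture pressure is emergent and near
# equal between arms by construction)
maintained:
  <<: *defaults
  E_inst: 16.6
  E_cv: 0.229      # sd 3.8 MPa from SEM 1.2, n 10
  eps_fracture_mean: 0.21
  eps_fracture_cv: 0.151   # sd 0.032 from SEM 0.01, n 10
  edge_failure_prob: 0.0
  n: 10

released:
  <<: *defaults
  E_inst: 11.4
  E_cv: 0.277      # sd 3.16 from SEM 1.0, n 10
  eps_fracture_mean: 0.29
  eps_fracture_cv: 0.109   # sd 0.032 from SEM 0.01, n 10
  edge_failure_prob: 0.0
  n: 10

# Creep-relaxation protocol (10 kPa hold); softer cultivar, visible creep
creep_default:
  <<: *defaults
  E_inst: 16.0
  creep_m: 0.005
  plastic_fraction: 0.0

# Other fruit crops (25 replicates per species; SEM-derived CVs)
sour_cherry_morellenfeuer:
  <<: *defaults
  E_inst: 5.9
  E_cv: 0.169
  eps_fracture_mean: 0.30
  eps_fracture_cv: 0.167
  n: 25

sour_cherry_ungarische_traubige:
  <<: *defaults
  E_inst: 3.5
  E_cv: 0.286
  eps_fracture_mean: 0.53
  eps_fracture_cv: 0.094
  n: 25

plum_hanita:
  <<: *defaults
  E_inst: 35.9
  E_cv: 0.446
  eps_fracture_mean: 0.15
  eps_fracture_cv: 0.333
  n: 25

grape_fanny:
  <<: *defaults
  E_inst: 21.5
  E_cv: 0.372
  eps_fracture_mean: 0.23
  eps_fracture_cv: 0.435
  n: 25

cape_gooseberry:
  <<: *defaults
  E_inst: 20.5
  E_cv: 0.195
  eps_fracture_mean: 0.25
  eps_fracture_cv: 0.2
  n: 25
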