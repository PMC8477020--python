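# Default configuration for the ptgtwin pipeline.
# Population constants are shared across patients; the six individualized
# parameters (set-points, gland size, degradation, production, clearance)
# are estimated per patient and only carry *reference* values here.

population:
  h: 7.0             # Hill steepness of Ca sensing (dimensionless)
  sigma_max: 0.5     # maximal secretion rate of stored PTH (1/min)
  k_act: 0.05        # quiescent -> active transition rate (1/min)
  k_deact: 0.05      # active -> quiescent transition rate (1/min)
  k_cl: 0.25         # plasma PTH clearance (1/min, ~2.8 min half-life)
  v_d: 3500.0        # PTH distribution volume (ml)
  lambda_max: 0.004  # maximal proliferation rate of quiescent cells (1/day)
  mu: 0.002          # apoptosis rate of quiescent cells (1/day)
  alpha_p: 1.0       # phosphate sensitivity of production (dimensionless)
  eps_d: 0.3         # fractional production suppression under calcitriol

# Reference values for the individualized parameter set (used as optimizer
# centers and as population centers for the synthetic cohort generator).
individual_reference:
  k_ca_setpoint: 1.15  # mmol/l
  p_opt: 1.5           # mmol/l
  gland_size0: 1.0     # dimensionless (healthy reference gland = 1)
  d0: 0.1              # maximal intracellular PTH degradation rate (1/min)
  p_rate: 370000.0     # PTH production scale (pg/min per unit gland mass)

solver:
  rtol: 1.0e-6
  atol: 1.0e-9

estimation:
  window_days: 180
  min_ipth_obs: 3
  min_ica_obs: 3
  min_phos_obs: 2
  vintage_gamma: 0.3      # prior gland mass = 1 + gamma * vintage_years
  vintage_sd_frac: 0.5    # prior sd as fraction of prior mean (weak prior)
  n_starts: 8             # Latin-hypercube multi-start count
  seed: 0
  max_nfev: 400
  ica_identifiability_sd: 0.005   # mmol/l; below this the set-point is flagged
  phos_identifiability_sd: 0.02   # mmol/l; below this p_opt is flagged
  bounds:
    k_ca_setpoint: [0.9, 1.5]
    p_opt: [0.8, 2.8]
    gland_size0: [0.25, 6.0]
    d0_frac: [0.5, 1.5]          # fraction of the reference d0
    p_rate_offset: [0.5, 1.5]    # multiplicative offset around the anchor
  obs_log_sd: 0.10        # nominal log-iPTH observation noise (MAP weight)
  obs_log_sd_floor: 1.0e-3  # lower bound for the re-estimated noise scale
  # population-scale shrinkage priors (MAP estimation); sparse windows
  # (~6 draws) cannot identify all parameters from likelihood alone
  priors:
    k_ca_setpoint_sd: 0.05       # mmol/l around the population set-point
    p_opt_sd: 0.3                # mmol/l around the reference p_opt
    d0_log_sd: 0.5               # lognormal around the reference d0
    p_rate_offset_log_sd: 0.5    # lognormal around offset 1

balance_calibration:
  enforce: true   # force mu = lambda_max * phi(set-point) = lambda_max / 2

prediction:
  horizon_days: 180
  week_halfwidth_days: 3
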