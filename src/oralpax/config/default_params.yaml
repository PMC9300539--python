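# Default parameter configuration for oralpax.
#
# Units: volumes L, clearances/flows L/h, times h, concentrations ng/mL,
# TSP-1 ng/mL per 10^6 platelets, variability as CV%.
#
# The `paclitaxel`, `physio`, `tsp1` and `random_effects` blocks carry the
# published population estimates of the oral paclitaxel + ritonavir PK/PD
# model.  The `ritonavir` and `iv_paclitaxel` blocks are SYNTHETIC plausible
# stand-ins for external literature models (user-supplied configuration):
# replace them with the published values when reproducing literature runs.

paclitaxel:
  alpha_first_dose: 1.68      # Weibull scale, 1st daily dose (h)
  alpha_second_dose: 1.97     # Weibull scale, 2nd daily dose (h)
  beta_solution: 2.53         # Weibull shape, drinking solution
  beta_asd: 3.57              # Weibull shape, tablet + capsule (ASD)
  clint0: 746.0               # uninhibited intrinsic clearance (L/h)
  ki: 375.0                   # ritonavir conc. of half-maximal inhibition (ng/mL)
  imax: 570.0                 # maximal inhibitory effect on CLint (L/h)
  vc: 128.0                   # central volume (L)
  q: 33.4                     # inter-compartmental clearance (L/h)
  vp: 375.0                   # peripheral volume (L)
  rf_solution: 1.0            # relative gut bioavailability, reference (FIX)
  rf_tablet: 0.97
  rf_capsule: 0.46
  rf_second_over_first: 0.59  # 2nd vs 1st daily dose bioavailability

physio:
  hepatic_blood_flow: 80.0    # Q_H (L/h), fixed
  liver_volume: 1.0           # V_H (L), fixed
  fraction_unbound: 0.13      # fu paclitaxel, fixed

tsp1:
  ec50: 284.0                 # paclitaxel conc. of half-maximal stimulation (ng/mL)
  baseline: 43.8              # E_BASE (ng/mL/10^6 platelets)
  turnover_time: 233.0        # fixed; kout = 1/233 h^-1

random_effects:
  bsv_cv:
    alpha: 35.1
    clint0: 25.1
    vc: 53.8
    rf_gut: 38.2
  bov_cv_rf_gut: 45.8
  sigma_prop_pk: 25.8
  bsv_ebase_cv: 28.2
  sigma_prop_pd: 13.8
  exact_lognormal: false

# SYNTHETIC stand-in for the external two-compartment ritonavir model with
# inverse-Gaussian density input (apparent oral parameters, F fixed to 1).
ritonavir:
  clearance: 10.0             # CL/F (L/h)
  vc: 60.0                    # Vc/F (L)
  q_inter: 8.0                # Q/F (L/h)
  vp: 40.0                    # Vp/F (L)
  bioavailable_fraction: 1.0
  mean_absorption_time: 1.2   # h
  input_shape: 0.4            # relative variance of the IG input density

# SYNTHETIC stand-in for the external three-compartment IV paclitaxel model.
iv_paclitaxel:
  vc: 16.0
  v2: 57.0
  v3: 260.0
  q2: 16.0
  q3: 11.0
  elimination: saturable
  vmax: 20000.0               # ug/h
  km: 1000.0                  # ng/mL
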