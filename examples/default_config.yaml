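# Complete default run configuration.
# Loading this file is identical to loading an empty file: every value below
# is the shipped default, listed with its units so overrides are easy.

geometry:
  V: 0.008              # water volume (m^3) = 8 L
  H: 0.16297466172610084  # water height (m) = V / A_sed
  A_sed: 0.04908738521234052  # sediment surface (m^2), 25 cm diameter
  A_peri: 0.128         # colonizable wall area (m^2) = pi * d * H
  A_strip: 0.045        # sampled periphyton strip area (m^2), 3 x 150 cm^2
  I_surface: 77.2       # surface irradiance (umol photons m^-2 s^-1)
  photoperiod: 0.6666666666666666  # lit fraction of the day (16h:8h)

groups:                 # rates in d^-1 at T_ref unless noted
  phyto_alpha:          # fast-growing, herbicide-sensitive phytoplankton
    p_max: 1.5
    l_d0: 0.05
    l_exu0: 0.03
    q_P: 0.01           # mg P per mg C
    K_P: 5.0            # mg P m^-3
    K_I: 40.0           # umol m^-2 s^-1
    C_max: null
    sigma_epi: null
    w_live: 0.02        # sinking velocity, live cells (m d^-1)
    w_dead: 0.1         # sinking velocity, dead cells (m d^-1)
    Q10_growth: 2.0
    Q10_loss: 2.0
    T_ref: 22.0         # degC
  phyto_beta:           # slow-growing, herbicide-resistant phytoplankton
    p_max: 1.0
    l_d0: 0.05
    l_exu0: 0.03
    q_P: 0.01
    K_P: 5.0
    K_I: 40.0
    C_max: null
    sigma_epi: null
    w_live: 0.02
    w_dead: 0.1
    Q10_growth: 2.0
    Q10_loss: 2.0
    T_ref: 22.0
  periphyton:           # wall biofilm
    p_max: 0.8
    l_d0: 0.03
    l_exu0: 0.02
    q_P: 0.01
    K_P: 10.0
    K_I: 40.0
    C_max: 2000.0       # carrying areal density (mg C m^-2)
    sigma_epi: null
    w_live: 0.0
    w_dead: 0.0
    Q10_growth: 2.0
    Q10_loss: 2.0
    T_ref: 22.0
  epiphyton:            # biofilm on macrophyte surfaces
    p_max: 0.8
    l_d0: 0.03
    l_exu0: 0.02
    q_P: 0.01
    K_P: 10.0
    K_I: 40.0
    C_max: 1000.0
    sigma_epi: null
    w_live: 0.0
    w_dead: 0.0
    Q10_growth: 2.0
    Q10_loss: 2.0
    T_ref: 22.0
  macrophytes:          # rooted submerged plants
    p_max: 0.15
    l_d0: 0.01
    l_exu0: 0.01
    q_P: 0.005          # plant tissue is P-poorer than algae
    K_P: 5.0
    K_I: 30.0
    C_max: null
    sigma_epi: 0.0001   # colonizable surface per plant C (m^2 per mg C)
    w_live: 0.0
    w_dead: 0.0
    Q10_growth: 2.0
    Q10_loss: 2.0
    T_ref: 22.0

decomposition:          # biodegradation of detritus, d^-1 at T_ref
  b_dead0: {phyto_alpha: 0.05, phyto_beta: 0.05, periphyton: 0.05,
            epiphyton: 0.05, macrophytes: 0.05}
  b_exu0: {phyto_alpha: 0.1, phyto_beta: 0.1, periphyton: 0.1,
           epiphyton: 0.1, macrophytes: 0.1}
  Q10_b: 2.0
  T_ref: 22.0

light:
  k_bg: 0.5             # background extinction (m^-1)
  k_chl: 0.0004         # extinction per live phytoplankton C (m^2 mg^-1)
  k_epi: 0.0004         # extinction of the epiphyton layer (m^2 mg^-1)

initial:
  phyto_total: 10.0     # mg C m^-3, split over the present phyto groups
  periphyton: 10.0      # mg C m^-2
  epiphyton: 1.0        # mg C, whole microcosm
  macrophytes: 200.0    # mg C, whole microcosm (planted shoots)
  P_d: 50.0             # mg P m^-3, equals the first nutrient pulse

dose_response:
  base_ec50: 3.0        # ug L^-1, sensitive anchor (EC20 0.75 at hill 1)
  hill: 1.0
  tolerance_final_factor: 16.0  # EC50_final / EC50_initial under D scenarios
  kappa_tol: 40.0       # tolerance pace; tau = kappa_tol / p_max (d)
  theta_T: 2.0          # warm-treatment EC50 multiplier under '2' scenarios

toxicant:
  loss_frac_application: 0.1  # immediate loss at application
  k_decay: null         # d^-1; null -> 70% remaining at day 18

dosing:
  P_per_event: 50.0     # mg P m^-3 per twice-weekly pulse
  NO3_N_per_event: 0.0  # mg m^-3, reporting only

solver:
  rtol: 1.0e-06
  atol: 1.0e-09
  method: LSODA
  samples_per_day: 4

duration_d: 19.0        # exposure length (d)
endpoint_day: 19.0      # sampling day for endpoint biomass
seed: 0
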