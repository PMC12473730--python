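# Default reference athlete for the planar bilateral-symmetric model.
# version: 1
#
# Segment mass/length fractions are Winter-style anthropometrics; the three
# leg segments lump BOTH legs (masses doubled), so the fractions sum to 1.
# Muscle parameters are literature-plausible group-level values for one leg
# (forces in N, lengths in m, constant moment arms in m,
# extension/plantarflexion-positive).
model:
  height: 1.80
  mass: 75.0
  gravity: 9.81
  ankle_height_frac: 0.039      # ankle joint height above ground / stature
  ankle_from_heel_frac: 0.25    # ankle x-position along the foot, of foot length
  reference_posture_deg: {hip: 45.0, knee: 60.0, ankle: 10.0}
  segments:
    foot:  {length_frac: 0.152, mass_frac: 0.029, com_frac: 0.50, gyration_frac: 0.475}
    shank: {length_frac: 0.246, mass_frac: 0.093, com_frac: 0.433, gyration_frac: 0.302}
    thigh: {length_frac: 0.245, mass_frac: 0.200, com_frac: 0.433, gyration_frac: 0.323}
    hat:   {length_frac: 0.470, mass_frac: 0.678, com_frac: 0.400, gyration_frac: 0.496}
  curves:
    fl_width: 0.45
    fv_shape: 0.25
    ecc_plateau: 1.4
    passive_strain_max: 0.6
    passive_exponent: 4.0
  muscles:
    gluteus_maximus:
      {F_max: 4500, l_opt: 0.140, l_slack: 0.110, alpha0_deg: 5,
       moment_arms: {hip: 0.060}}
    iliopsoas:
      {F_max: 2000, l_opt: 0.100, l_slack: 0.130, alpha0_deg: 8,
       moment_arms: {hip: -0.040}}
    hamstrings:
      {F_max: 4000, l_opt: 0.100, l_slack: 0.330, alpha0_deg: 10,
       moment_arms: {hip: 0.055, knee: -0.030}}
    rectus_femoris:
      {F_max: 1600, l_opt: 0.080, l_slack: 0.340, alpha0_deg: 9,
       moment_arms: {hip: -0.040, knee: 0.040}}
    vasti:
      {F_max: 7000, l_opt: 0.090, l_slack: 0.220, alpha0_deg: 12,
       moment_arms: {knee: 0.045}}
    gastrocnemius:
      {F_max: 2500, l_opt: 0.055, l_slack: 0.380, alpha0_deg: 15,
       moment_arms: {knee: -0.020, ankle: 0.045}}
    soleus:
      {F_max: 5000, l_opt: 0.050, l_slack: 0.260, alpha0_deg: 22,
       moment_arms: {ankle: 0.040}}
    tibialis_anterior:
      {F_max: 1500, l_opt: 0.070, l_slack: 0.220, alpha0_deg: 7,
       moment_arms: {ankle: -0.035}}
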