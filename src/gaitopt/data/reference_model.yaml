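# Default planar (sagittal) musculoskeletal model: reference anthropometry,
# muscle set, foot-ground contact, prosthesis and condition definitions.
#
# Segment mass/length fractions follow standard planar gait anthropometry
# tables (Winter-style).  Muscle-tendon parameters and moment arms are generic
# literature-scale values; they are ASSUMPTIONS where the study they emulate
# reports none (notably all prosthetic component masses, which are set as a
# fraction of the intact segments).  Everything here can be overridden by a
# user config merged on top.

reference:
  mass: 75.0     # kg   anthropometry-table reference subject
  height: 1.75   # m

gravity: 9.81    # m s^-2

segments:        # fractions of body mass / height; com measured from proximal end
  hat:   {mass_frac: 0.6780, length_frac: 0.400, com_frac: 0.374, rog_frac: 0.350}
  thigh: {mass_frac: 0.1000, length_frac: 0.245, com_frac: 0.433, rog_frac: 0.323}
  shank: {mass_frac: 0.0465, length_frac: 0.246, com_frac: 0.433, rog_frac: 0.302}
  foot:  {mass_frac: 0.0145, length_frac: 0.152, com_frac: 0.500, rog_frac: 0.475}

pelvis:
  ty_range: [0.60, 1.20]        # m, vertical excursion bounds of the hip center
  tilt_range_deg: [-30.0, 30.0]

joints:          # sagittal pin joints; flexion positive (dorsiflexion for ankle)
  hip:
    range_deg: [-30.0, 120.0]
    passive: {k1: 2.0, k2: 5.0, q_lower_deg: -20.0, q_upper_deg: 110.0, b: 0.10, k_lin: 0.0}
  knee:
    range_deg: [-15.0, 140.0]
    passive: {k1: 3.0, k2: 5.0, q_lower_deg: -5.0, q_upper_deg: 137.5, b: 0.10, k_lin: 0.0}
  ankle:
    range_deg: [-60.0, 40.0]
    passive: {k1: 2.0, k2: 5.0, q_lower_deg: -50.0, q_upper_deg: 35.0, b: 0.10, k_lin: 0.0}

# Per-leg muscle set covering the sagittal functional groups.  Moment arm of
# muscle m about joint j is r(q_j) = r0 + r1*q_j (meters, q in rad); the
# musculotendon length polynomial is l_mt(q) = l_ref - sum_j (r0*q_j + r1*q_j^2/2)
# so that r = -dl/dq holds exactly.  l_ref places the fiber at optimal length
# with the tendon slack at the neutral pose (q = 0).
muscles:
  iliopsoas:            {f_max_iso: 1500.0, l_opt: 0.100, l_ts: 0.130, alpha_opt_deg:  8.0, v_max: 10.0,
                         arms: {hip: [0.045, 0.0]}}
  gluteus_maximus:      {f_max_iso: 1900.0, l_opt: 0.147, l_ts: 0.125, alpha_opt_deg:  3.0, v_max: 10.0,
                         arms: {hip: [-0.060, 0.0]}}
  hamstrings:           {f_max_iso: 2600.0, l_opt: 0.100, l_ts: 0.310, alpha_opt_deg: 10.0, v_max: 10.0,
                         arms: {hip: [-0.060, 0.0], knee: [0.035, 0.0]}}
  rectus_femoris:       {f_max_iso: 1200.0, l_opt: 0.081, l_ts: 0.350, alpha_opt_deg:  5.0, v_max: 10.0,
                         arms: {hip: [0.035, 0.0], knee: [-0.042, 0.0]}}
  vasti:                {f_max_iso: 4500.0, l_opt: 0.093, l_ts: 0.220, alpha_opt_deg:  4.0, v_max: 10.0,
                         arms: {knee: [-0.045, 0.0]}}
  biceps_femoris_sh:    {f_max_iso:  800.0, l_opt: 0.110, l_ts: 0.100, alpha_opt_deg: 23.0, v_max: 10.0,
                         arms: {knee: [0.035, 0.0]}}
  gastrocnemius:        {f_max_iso: 2500.0, l_opt: 0.060, l_ts: 0.390, alpha_opt_deg: 12.0, v_max: 10.0,
                         arms: {knee: [0.020, 0.0], ankle: [-0.048, 0.0]}}
  soleus:               {f_max_iso: 3500.0, l_opt: 0.050, l_ts: 0.250, alpha_opt_deg: 25.0, v_max: 10.0,
                         arms: {ankle: [-0.048, 0.0]}}
  tibialis_anterior:    {f_max_iso: 1300.0, l_opt: 0.098, l_ts: 0.220, alpha_opt_deg:  5.0, v_max: 10.0,
                         arms: {ankle: [0.037, 0.0]}}

contacts:        # spheres on the foot segment; location in the foot frame (m at
                 # reference height, x forward from the ankle, y up), scaled with height
  heel: {location: [-0.050, -0.025], radius: 0.032, stiffness: 2.0e5, dissipation: 2.0, mu: 0.8, v_t: 0.10}
  toe:  {location: [ 0.160, -0.025], radius: 0.032, stiffness: 2.0e5, dissipation: 2.0, mu: 0.8, v_t: 0.10}

prosthesis:
  d_mpk: 1.0          # N m s rad^-1, variable-damping knee coefficient (REF setting)
  tau_mpk: 0.030      # s, first-order knee-activation time constant
  mass_ratio: 0.60    # prosthetic shank/foot mass relative to intact segments (assumption)
  mpk_passive:        # hyperextension stop + flexion limit of the prosthetic knee
    {k1: 3.0, k2: 8.0, q_lower_deg: -2.0, q_upper_deg: 137.5, b: 0.20, k_lin: 0.0}
  esr_passive:        # energy-storage-and-return foot as an elastic ankle
    {k1: 1.0, k2: 5.0, q_lower_deg: -40.0, q_upper_deg: 30.0, b: 1.0, k_lin: 300.0}

conditions:
  REF:   {d_mpk: 1.00}
  DACT:  {d_mpk: 0.75}
  SKG15: {knee_limit_deg: 14.9}
  SKG30: {knee_limit_deg: 30.0}
  SKG35: {knee_limit_deg: 35.0}
  SKGI:  {knee_limit_deg: 20.0, orthosis_mass_thigh: 0.3, orthosis_mass_shank: 0.3}
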