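# Prone-position scenario: cardiac-limited (preload-unresponsive) baseline.
# The chest wall is already stiff (E_CW/E_RS = 0.5), so supine pericardial
# pressure = 15 * 0.5 - 2.5 = 5.0 mmHg and the operating point sits on the
# cardiac plateau. Pronation raises P_MSF and R_VR but leaves cardiac
# function and the pericardial components unchanged: the model predicts
# P_RA rises while Q is exactly unchanged.
patient:
  label: cardiac-limited baseline
  body_mass: 70.0
  vr_curve:
    p_msf: 10.0
    r_vr: 0.1
    p_crit: -2.0
  cardiac:
    pericardium:
      p_pl: -2.5
      p_aw: 15.0
      e_cw: 0.5
      e_rs: 1.0
      p_pc_el: 0.0
    r_cardiac: 0.02857142857142857
    p_ra_plat: 6.0
prone:
  name: prone_position
  delta_p_msf: 6.0
  r_vr_factor: 1.2
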