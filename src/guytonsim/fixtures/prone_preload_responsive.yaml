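# Prone-position scenario: preload-responsive baseline.
# Supine pericardial pressure = 15 * 0.2 - 2.5 = 0.5 mmHg.
# Pronation raises P_MSF and R_VR, stiffens the chest wall
# (E_CW/E_RS 0.2 -> 0.5) and improves cardiac function (R_cardiac x0.8).
# Intervention magnitudes are illustrative scenario choices; only the
# direction of the response (Q and P_RA both rise) is a model prediction.
patient:
  label: preload-responsive baseline
  body_mass: 70.0
  vr_curve:
    p_msf: 8.0
    r_vr: 0.1
    p_crit: -2.0
  cardiac:
    pericardium:
      p_pl: -2.5
      p_aw: 15.0
      e_cw: 0.2
      e_rs: 1.0
      p_pc_el: 0.0
    r_cardiac: 0.02857142857142857
    p_ra_plat: 10.0
prone:
  name: prone_position
  delta_p_msf: 6.0
  r_vr_factor: 1.2
  r_cardiac_factor: 0.8
  delta_e_cw_ratio: 0.3
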