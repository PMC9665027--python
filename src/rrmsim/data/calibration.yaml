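version: 6
factors:
  p_auto_base: 0.0007
  lesion_mult: 1.3
  kill_mult_high: 1.05
  age_gradient: 0.18
  treg_gradient: 0.05
  present_self_max: 0.138
  death_plasma_ocb: 0.006
  death_plasma_no_ocb: 0.012
combos:
  HIGH|PRESENT|18-29:
    p_auto: 0.00091
    p_kill_ctl: 0.189
    p_kill_th: 0.084
    setpoint_B: 260
    setpoint_TH: 307
    setpoint_TREG: 63
    death_plasma: 0.006
    p_present_self_max: 0.138
  HIGH|PRESENT|30-39:
    p_auto: 0.00091
    p_kill_ctl: 0.189
    p_kill_th: 0.084
    setpoint_B: 220
    setpoint_TH: 260
    setpoint_TREG: 60
    death_plasma: 0.006
    p_present_self_max: 0.138
  HIGH|PRESENT|40-49:
    p_auto: 0.00091
    p_kill_ctl: 0.189
    p_kill_th: 0.084
    setpoint_B: 180
    setpoint_TH: 213
    setpoint_TREG: 57
    death_plasma: 0.006
    p_present_self_max: 0.138
  HIGH|ABSENT|18-29:
    p_auto: 0.00091
    p_kill_ctl: 0.189
    p_kill_th: 0.084
    setpoint_B: 260
    setpoint_TH: 307
    setpoint_TREG: 63
    death_plasma: 0.012
    p_present_self_max: 0.138
  HIGH|ABSENT|30-39:
    p_auto: 0.00091
    p_kill_ctl: 0.189
    p_kill_th: 0.084
    setpoint_B: 220
    setpoint_TH: 260
    setpoint_TREG: 60
    death_plasma: 0.012
    p_present_self_max: 0.138
  HIGH|ABSENT|40-49:
    p_auto: 0.00091
    p_kill_ctl: 0.189
    p_kill_th: 0.084
    setpoint_B: 180
    setpoint_TH: 213
    setpoint_TREG: 57
    death_plasma: 0.012
    p_present_self_max: 0.138
  LOW_MEDIUM|PRESENT|18-29:
    p_auto: 0.0007
    p_kill_ctl: 0.18
    p_kill_th: 0.08
    setpoint_B: 260
    setpoint_TH: 307
    setpoint_TREG: 63
    death_plasma: 0.006
    p_present_self_max: 0.138
  LOW_MEDIUM|PRESENT|30-39:
    p_auto: 0.0007
    p_kill_ctl: 0.18
    p_kill_th: 0.08
    setpoint_B: 220
    setpoint_TH: 260
    setpoint_TREG: 60
    death_plasma: 0.006
    p_present_self_max: 0.138
  LOW_MEDIUM|PRESENT|40-49:
    p_auto: 0.0007
    p_kill_ctl: 0.18
    p_kill_th: 0.08
    setpoint_B: 180
    setpoint_TH: 213
    setpoint_TREG: 57
    death_plasma: 0.006
    p_present_self_max: 0.138
  LOW_MEDIUM|ABSENT|18-29:
    p_auto: 0.0007
    p_kill_ctl: 0.18
    p_kill_th: 0.08
    setpoint_B: 260
    setpoint_TH: 307
    setpoint_TREG: 63
    death_plasma: 0.012
    p_present_self_max: 0.138
  LOW_MEDIUM|ABSENT|30-39:
    p_auto: 0.0007
    p_kill_ctl: 0.18
    p_kill_th: 0.08
    setpoint_B: 220
    setpoint_TH: 260
    setpoint_TREG: 60
    death_plasma: 0.012
    p_present_self_max: 0.138
  LOW_MEDIUM|ABSENT|40-49:
    p_auto: 0.0007
    p_kill_ctl: 0.18
    p_kill_th: 0.08
    setpoint_B: 180
    setpoint_TH: 213
    setpoint_TREG: 57
    death_plasma: 0.012
    p_present_self_max: 0.138
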