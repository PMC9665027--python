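# Versioned engine parameter file: the shipped default configuration of the
# immune core and RRMS pathology layer.  All probabilities are per timestep
# (one timestep = 1 simulated day) unless named *_days.
# These values are calibration products of this package, chosen so that the
# population-level relapse statistics of the shipped presets land on their
# documented targets; they are not measurements.
version: 3

# -- discretisation ---------------------------------------------------------
steps_per_day: 1
grid_side: 16

# -- receptor space ---------------------------------------------------------
receptor_length: 12
bind_threshold: 0.9166666666666666   # 11/12 complementary bits
neg_threshold: 1.0                   # thymic deletion of exact complements only
self_antigen: 2763                   # oligodendrocyte-associated epitope
mimicry_flips: 0                     # Hamming distance of the EBV epitope from self
p_auto: 0.002                        # near-complement bias of new B/TH/CTL receptors

# -- homeostasis ------------------------------------------------------------
setpoint_B: 220
setpoint_TH: 260
setpoint_TREG: 60
setpoint_CTL: 180
setpoint_NK: 90
setpoint_APC: 120
death_resting: 0.012
death_activated: 0.04
death_activated_wm: 0.07             # effectors burn out faster in tissue
death_anergic: 0.024
death_plasma: 0.02

# -- EBV trigger and antigen presentation -----------------------------------
ebv_enabled: true                    # disable for no-trigger null runs
ebv_window_days: 365                 # trigger uniform in the first run-in year
viral_init: 1.0
viral_growth: 1.25
viral_cap: 5000.0
viral_clear_eff: 0.25                # per activated virus-binding lymphocyte
viral_clear_nk: 0.001
viral_clear_ab: 0.0002              # per antibody-titer unit                # per peripheral NK cell
viral_present_K: 50.0                # half-saturation of APC viral presentation
p_present_viral_max: 0.70            # APC viral-presentation ceiling
debris_decay: 0.998                  # myelin debris persistence per step
debris_per_kill: 1.5
p_present_self_max: 0.13             # APC self-epitope presentation at high debris
debris_K: 12.0
debris_hill: 2.0                     # cooperativity of debris-driven presentation

# -- activation -------------------------------------------------------------
p_act_th: 0.5
p_act_ctl: 0.35
p_act_b: 0.35
p_act_treg: 0.04
il2_K: 5.0
il2_gate_floor: 0.4
p_switch_plasma: 0.08
isotype_probs: [0.5, 0.35, 0.15]     # IgM, IgG, IgA at class switch

# -- proliferation ----------------------------------------------------------
p_dup_th: 0.5
p_dup_ctl: 0.5
p_dup_b: 0.35
p_dup_treg: 0.3
dup_window: 10                        # steps after activation during which clones expand
crowd_cap_mult: 2.5                  # duplication stalls near this multiple of set-point

# -- regulation -------------------------------------------------------------
p_sup: 0.12
tgfb_K: 5.0
tgfb_gate_floor: 0.3

# -- trafficking ------------------------------------------------------------
p_mig_eff: 0.10                      # activated TH/CTL periphery -> white matter

# -- white matter / oligodendrocytes ----------------------------------------
n_oligo: 200
p_kill_ctl: 0.18
p_kill_th: 0.08
p_remyelinate: 0.008

# -- cytokines and antibodies -----------------------------------------------
secrete_il2_th: 3.0
secrete_ifng_th: 1.5
secrete_ifng_ctl: 2.0
secrete_tgfb_treg: 2.5
cytokine_decay: 0.88
cytokine_diffusion: 0.3
secrete_ab_plasma: 1.0
ab_decay: 0.98

# -- relapse definition -----------------------------------------------------
relapse_theta: 0.05                  # fractional oligodendrocyte loss
relapse_window_days: 14
relapse_min_gap_days: 30

# -- reporting --------------------------------------------------------------
cells_per_agent_ul: 1.0              # scale factor agents -> cells/uL in exports
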