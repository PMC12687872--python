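cm: 2.0
densities:
  acd_stem:
    g_pas: 0.00125
    gk: 0.004
    gna: 0.01
  ais_dist:
    g_pas: 0.00125
    gk: 0.25
    gna: 0.65
  ais_prox:
    g_pas: 0.00125
    gk: 0.12
    gna: 0.55
  apical1:
    g_pas: 0.00125
    gk: 0.002
    gna: 0.005
  apical2:
    g_pas: 0.00125
    gk: 0.002
    gna: 0.005
  apical3:
    g_pas: 0.00125
    gk: 0.002
    gna: 0.005
  axon_distal:
    g_pas: 0.00125
    gk: 0.03
    gna: 0.06
  balance_stub:
    g_pas: 0.00125
    gk: 0.002
    gna: 0.005
  basal_acd:
    g_pas: 0.00125
    gk: 0.002
    gna: 0.005
  basal_nonacd:
    g_pas: 0.00125
    gk: 0.002
    gna: 0.005
  hillock:
    g_pas: 0.00125
    gk: 0.06
    gna: 0.3
  soma:
    g_pas: 0.00125
    gk: 0.02
    gna: 0.06
  tuft:
    g_pas: 0.00125
    gk: 0.002
    gna: 0.003
e_pas: -70.0
ek: -90.0
ena: 55.0
na_shift: -5.0
na_shift_mode: activation
ra: 150.0
v_init: -70.0
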