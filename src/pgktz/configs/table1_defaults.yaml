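# Default configuration: published kinetic constants and the in vitro
# simulation protocol (0.04 uM PGK1, 1 mM ADP, 80 uM clamped 1,3-BPG,
# 8-point terazosin grid, 60 s endpoint).
parameters:
  a_plus: 6.1
  a_minus: 38.0
  b_plus: 170.0
  b_minus: 160.0
  c_plus: 450.0
  c_minus: 14.0
  d_plus: 4.1
  d_minus: 270.0
  k_plus: 5.0
  k_minus: 5.0
  eta: 562.0
initial_conditions:
  E: 0.04 uM
  ADP: 1 mM
  BPG: 80 uM
  ATP: 0
  PG: 0
  TZ: 0
clamped: [BPG]
tz_grid: [0, 2.5 nM, 25 nM, 50 nM, 0.25 uM, 0.5 uM, 2.5 uM, 25 uM]
simulation:
  t_end: 60.0
  rtol: 1.0e-9
  atol: 1.0e-12
  method: LSODA
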