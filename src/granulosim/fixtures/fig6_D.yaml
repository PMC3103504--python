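model: detailed
name: fig6_D
params:
  k_2a: 2.1
settle_first: true
pulses:
- channel: A
  amplitude: 100.0
  t_on: 20.0
  t_off: 70.0
- channel: I_delta
  amplitude: 29.0
  t_on: 100.0
  t_off: 120.0
t_end: 800.0
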