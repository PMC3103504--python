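model: minimal
name: fig1
initial_state: 0.34
pulses:
- channel: A
  amplitude: 4.0
  t_on: 5.0
  t_off: 10.0
t_end: 60.0
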