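# Small-conductance calcium-activated potassium channel (SK).
# Purely calcium-gated; Hill activation on submembrane free calcium.
name: sk
conductance_param: g_sk
reversal_mV: -90.0
carries_calcium: false
gates:
  - name: z
    exponent: 1
    kind: calcium
    activation: {kd_mM: 4.0e-4, hill: 4.0, tau_ms: 5.0}
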