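# Delayed-rectifier potassium channel.
name: kdr
conductance_param: g_kdr
reversal_mV: -90.0
carries_calcium: false
gates:
  - name: n
    exponent: 4
    kind: voltage
    inf: {vhalf_mV: -32.0, slope_mV: 10.0}
    tau: {min_ms: 0.3, amp_ms: 2.0, vpeak_mV: -55.0, kleft_mV: 25.0, kright_mV: 25.0}
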