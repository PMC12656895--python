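# A-type (fast inactivating) potassium channel.
name: ka
conductance_param: g_ka
reversal_mV: -90.0
carries_calcium: false
gates:
  - name: a
    exponent: 1
    kind: voltage
    inf: {vhalf_mV: -30.0, slope_mV: 10.0}
    tau: {min_ms: 0.3, amp_ms: 1.2, vpeak_mV: -40.0, kleft_mV: 20.0, kright_mV: 20.0}
  - name: b
    exponent: 1
    kind: voltage
    inf: {vhalf_mV: -74.0, slope_mV: -8.0}
    tau: {min_ms: 6.0, amp_ms: 30.0, vpeak_mV: -60.0, kleft_mV: 20.0, kright_mV: 20.0}
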