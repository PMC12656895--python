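# M-type (muscarinic-sensitive, slow non-inactivating) potassium channel.
name: km
conductance_param: g_km
reversal_mV: -90.0
carries_calcium: false
gates:
  - name: m
    exponent: 1
    kind: voltage
    inf: {vhalf_mV: -35.0, slope_mV: 9.0}
    tau: {min_ms: 20.0, amp_ms: 80.0, vpeak_mV: -40.0, kleft_mV: 20.0, kright_mV: 20.0}
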