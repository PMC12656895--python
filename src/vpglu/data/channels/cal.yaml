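# L-type (high-voltage-activated) calcium channel; ohmic E_Ca approximation.
name: cal
conductance_param: g_cal
reversal_mV: 120.0
carries_calcium: true
gates:
  - name: c
    exponent: 1
    kind: voltage
    inf: {vhalf_mV: -15.0, slope_mV: 5.0}
    tau: {min_ms: 0.6, amp_ms: 1.5, vpeak_mV: -15.0, kleft_mV: 15.0, kright_mV: 15.0}
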