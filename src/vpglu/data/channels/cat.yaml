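# T-type (low-voltage-activated, transient) calcium channel.
# Steep activation and near-complete resting inactivation keep the window
# current small relative to the submembrane shell's extrusion capacity.
name: cat
conductance_param: g_cat
reversal_mV: 120.0
carries_calcium: true
gates:
  - name: s
    exponent: 2
    kind: voltage
    inf: {vhalf_mV: -44.0, slope_mV: 5.0}
    tau: {min_ms: 1.5, amp_ms: 3.0, vpeak_mV: -45.0, kleft_mV: 15.0, kright_mV: 15.0}
  - name: u
    exponent: 1
    kind: voltage
    inf: {vhalf_mV: -80.0, slope_mV: -4.0}
    tau: {min_ms: 12.0, amp_ms: 30.0, vpeak_mV: -75.0, kleft_mV: 15.0, kright_mV: 15.0}
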