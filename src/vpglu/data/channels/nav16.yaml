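# Nav1.6-type fast transient sodium channel (axon hillock).
# Fast activation/inactivation (m, h) generate the spike; h recovery is
# steep around -53 mV, so shallow interspike troughs leave the channel
# inactivated.  The slow inactivation gate (s) erodes mainly at spike
# voltages and is what makes sustained high-rate firing collapse into
# depolarization block.
name: nav16
conductance_param: g_nav16
reversal_mV: 60.0
carries_calcium: false
gates:
  - name: m
    exponent: 3
    kind: voltage
    inf: {vhalf_mV: -35.0, slope_mV: 8.0}
    tau: {min_ms: 0.04, amp_ms: 0.15, vpeak_mV: -38.0, kleft_mV: 15.0, kright_mV: 15.0}
  - name: h
    exponent: 1
    kind: voltage
    inf: {vhalf_mV: -53.0, slope_mV: -5.0}
    tau: {min_ms: 0.3, amp_ms: 2.2, vpeak_mV: -58.0, kleft_mV: 16.0, kright_mV: 16.0}
  - name: s
    exponent: 1
    kind: voltage
    inf: {vhalf_mV: -48.0, slope_mV: -9.0}
    tau: {min_ms: 25.0, amp_ms: 800.0, vpeak_mV: -55.0, kleft_mV: 10.0, kright_mV: 30.0}
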