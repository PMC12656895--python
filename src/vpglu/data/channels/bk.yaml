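# Large-conductance calcium- and voltage-activated potassium channel (BK).
# At baseline calcium the activation midpoint sits far above spike peak, so
# the channel opens essentially only when a spike-evoked calcium transient
# shifts the midpoint leftward (strong shift per decade of calcium): BK acts
# as a calcium-triggered repolarization reserve, which is what a fast
# calcium buffer removes.
name: bk
conductance_param: g_bk
reversal_mV: -90.0
carries_calcium: false
gates:
  - name: w
    exponent: 1
    kind: voltage_cashift
    inf: {vhalf_mV: 30.0, slope_mV: 11.0, shift_mV_per_decade: 60.0, ca_ref_mM: 1.0e-3}
    tau: {min_ms: 0.6, amp_ms: 2.0, vpeak_mV: -20.0, kleft_mV: 18.0, kright_mV: 18.0}
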