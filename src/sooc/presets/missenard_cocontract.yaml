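# Fast co-contracted elbow reach: 40 deg in 400 ms, strong terminal
# variance penalty (q_var = 500).
preset: missenard_cocontract
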