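# Two-joint reach through a divergent force field (beta = 40 N/m) with
# endpoint-variance penalty q_var = 1e4.
preset: burdet_df
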