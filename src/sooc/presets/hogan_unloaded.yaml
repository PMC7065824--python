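# Maintain the unloaded forearm upright for 5 s without state feedback.
preset: hogan_unloaded
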