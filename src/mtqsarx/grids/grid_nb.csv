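alpha,1,0.5,0.1
fit_prior,True,False
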