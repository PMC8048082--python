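C,0.1,1,10,100,1000
gamma,1,0.1,0.01,0.001
kernel,rbf,linear,poly,sigmoid
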