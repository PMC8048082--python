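activation,identity,logistic,tanh,relu
solver,sgd,adam
alpha,0.0001,0.001,0.01,1
learning_rate,constant,adaptive,invscaling
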