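bootstrap,True,False
criterion,gini,entropy
max_depth,10,30,50,70,90,100,200,None
max_features,sqrt,log2
min_samples_leaf,1,2,4
min_samples_split,2,5,10
n_estimators,50,100,200,500
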