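loss,log_loss,exponential
learning_rate,0.01,0.05,0.1,0.2
min_samples_split,0.1,0.2,0.3,0.4,0.5
min_samples_leaf,0.1,0.2,0.3,0.4,0.5
max_depth,3,5,8
max_features,log2,sqrt
criterion,friedman_mse,squared_error
subsample,0.5,0.6,0.8
n_estimators,50,100,200,300
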