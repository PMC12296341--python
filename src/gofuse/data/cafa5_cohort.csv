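# Published CAFA5 cohort statistics used as fixed inputs: tagged protein
# count, species count, default pruning frequency and the train/test
# split sizes.
n_proteins,n_species,prune_threshold,n_train,n_test
142246,3156,21,128020,14225
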