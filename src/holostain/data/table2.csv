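true_class,GNB,GPC_clusters,GPC_pairs_chains,Indeterminate
GNB,34,0,0,2
GPC_clusters,0,21,0,3
GPC_pairs_chains,1,0,32,3
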