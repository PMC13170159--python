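true_class,GNB,GPC_clusters,GPC_pairs_chains
GNB,14,1,0
GPC_clusters,1,40,1
GPC_pairs_chains,1,1,6
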