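# Reported summary counts from the chronic-UV mouse skin time course
# (GEO accession GSE58915).  These are published inputs, not quantities
# this package recomputes: reproducing them would require the accession
# matrix plus preprocessing steps that were not fully specified.
n_deg_total: 637
n_down: 514
n_up: 123
# kinetic clusters 4 and 6 (the two week-2-recovery repression kinetics)
clusters_4_6_size: 175
ecm_genes_in_down: 17
ecm_genes_in_clusters_4_6: 14
# candidate prediction
top50_n: 50
prediction_pool: 504
median_seed_rank: 39
optimal_threshold: 0.946
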