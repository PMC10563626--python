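{
 "interactome_size": 483,
 "synaptic_interactome_mouse": 89,
 "synaptic_interactome_combined": 92,
 "ppi_network_nodes": 66,
 "cluster_sizes": [
  23,
  13,
  14,
  16
 ],
 "min_cluster_size": 4,
 "string_min_score": 0.4,
 "mcl_inflation": 1.3,
 "filtered_candidate_genes": {
  "ASD": 461,
  "SCZ": 881,
  "PD": 74,
  "AD": 86
 },
 "associations_available": {
  "ASD": 1275,
  "SCZ": 4961,
  "PD": 494,
  "AD": 1988
 },
 "interactome_overlap_counts": {
  "SCZ": 20,
  "ASD": 12,
  "PD": 1,
  "AD": 1
 },
 "brain_regions": [
  "cerebral cortex",
  "hippocampal formation",
  "amygdala",
  "thalamus",
  "hypothalamus",
  "midbrain",
  "pons",
  "cerebellum",
  "medulla oblongata"
 ],
 "synapse_go_term": "GO:0045202"
}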