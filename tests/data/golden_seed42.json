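{
 "chiprx_scale_factors": {
  "DMSO": 0.719497,
  "JQ1": 1.0,
  "SN38": 0.717027,
  "SN38+JQ1": 0.794895
 },
 "conditions": {
  "DMSO": {
   "n_exonic": 5269,
   "n_nascent": 25886,
   "n_nonexonic": 58894,
   "n_reads": 64163,
   "nerd_index": 13.353321,
   "slam_index": 25.267741,
   "spikein": 4934
  },
  "JQ1": {
   "n_exonic": 3579,
   "n_nascent": 18203,
   "n_nonexonic": 41786,
   "n_reads": 45365,
   "nerd_index": -2.912741,
   "slam_index": -2.169668,
   "spikein": 3550
  },
  "SN38": {
   "n_exonic": 5006,
   "n_nascent": 27088,
   "n_nonexonic": 63084,
   "n_reads": 68090,
   "nerd_index": -267.420677,
   "slam_index": -270.032472,
   "spikein": 4951
  },
  "SN38+JQ1": {
   "n_exonic": 4621,
   "n_nascent": 25875,
   "n_nonexonic": 60195,
   "n_reads": 64816,
   "nerd_index": -244.829648,
   "slam_index": -247.305983,
   "spikein": 4466
  }
 },
 "dogs": {
  "condition": "SN38+JQ1",
  "median_dist_next_gene_control": 78637.0,
  "median_dist_next_gene_dog": 98110.5,
  "median_dog_length": 63000.0,
  "median_matching_distance": 0.244219,
  "n_called": 14,
  "n_high_stringency": 14,
  "n_true_dogs_expressed": 15,
  "precision": 1.0,
  "recall": 0.933333
 },
 "length_fc": {
  "ma_longest_decile": -0.035217,
  "ma_shortest_decile": 0.074719,
  "n_genes": 80
 },
 "n_expressed": 80,
 "n_genes": 80,
 "replication": {
  "DMSO": {
   "early_E_cpm_total": 835129.604366,
   "late_L_cpm_total": 824887.703537,
   "late_L_share": 0.824888
  },
  "JQ1": {
   "early_E_cpm_total": 839371.898579,
   "late_L_cpm_total": 828996.544672,
   "late_L_share": 0.828997
  },
  "SN38": {
   "early_E_cpm_total": 836896.598091,
   "late_L_cpm_total": 824688.208617,
   "late_L_share": 0.824688
  },
  "SN38+JQ1": {
   "early_E_cpm_total": 838566.883386,
   "late_L_cpm_total": 875139.693183,
   "late_L_share": 0.87514
  },
  "median_boundary_dist_control": 668088.5,
  "median_boundary_dist_dog": 845813.5,
  "n_segments": {
   "chr1": 10
  },
  "readthrough_direction_counts": {
   "late\u2192early": 2,
   "within-early": 6,
   "within-late": 6
  }
 }
}
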