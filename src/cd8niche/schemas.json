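{
  "cell_map": {
    "required_columns": ["cell_id", "x_um", "y_um", "compartment", "cell_type"],
    "notes": "per-cell spatial table; coordinates in micrometers, planar frame"
  },
  "state_scores": {
    "required_columns": ["cell_id", "transition", "state_label"],
    "notes": "per-cell signature scores plus rank-normalized transition in [0,1]"
  },
  "aggregates": {
    "required_columns": ["aggregate_id", "size", "centroid_x_um", "centroid_y_um",
                         "area_um2", "T_fraction", "class_label"],
    "notes": "one row per detected immune aggregate"
  },
  "aggregate_assignment": {
    "required_columns": ["cell_id", "aggregate_id"],
    "notes": "per-cell aggregate membership; -1 means unassigned"
  },
  "clonotypes": {
    "required_columns": ["clonotype_id", "size", "expanding"],
    "notes": "one row per clonotype; per-state count columns n_<state> when states supplied"
  },
  "anchor_ranking": {
    "required_columns": ["gene", "similarity"],
    "notes": "genes ranked by cosine similarity of loading columns to the anchor gene"
  },
  "enrichment": {
    "required_columns": ["gene_set", "es", "nes", "p", "fdr"],
    "notes": "ranked running-sum enrichment results, BH-corrected across the set family"
  },
  "rank_de": {
    "required_columns": ["gene", "U", "p", "fdr", "log2_fc"],
    "notes": "per-gene Mann-Whitney differential expression screen"
  }
}
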