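# netpharm demo configuration: a small fully synthetic end-to-end run.
# All stage inputs default to the files `simulate` writes in --out-dir.
seed: 1

simulate:
  itraq:
    n_proteins: 200
    frac_up: 0.1
    frac_down: 0.1
    up_fold: 2.0
    down_fold: 0.5
    noise_cv: 0.2
    n_batches: 10
    patients_per_batch: 3
  compounds:
    n_compounds: 20
    fp_length: 64
    n_similar: 20
  network:
    n_targets: 120
    n_disease_targets: 60
    n_overlap: 15
    planted_pathway_size: 10
    n_decoy_pathways: 15
  scenario:
    n_hubs: 12
    n_deps: 13
    n_key: 3

quant:
  thresholds:
    up: 1.2
    down: 0.8
    alpha: 0.05
    min_peptides: 2
    min_unused_score: 2.0
    min_consensus: 0.8333333333333334

screen:
  threshold: 0.8

hubs:
  stat: median

integrate:
  stat: median
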