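# Tuned LightGBM hyperparameters of the screen's reference cell-count
# classifier, shipped as a fixture for users attaching an external trainer.
general:
  boosting_type: gbdt
  objective: binary
  num_leaves: 191
  max_depth: 118
  learning_rate: 0.01679910379082482
  n_estimators: 12042
  random_state: 42
  data_sample_strategy: goss
  top_rate: 0.17018468861347003
regularization:
  lambda_l1: 14.825534539789798
  lambda_l2: 95.37157659523345
  linear_lambda: 70.86772503160189
  drop_rate: 0.73844801734339
  max_drop: 1267
  skip_drop: 0.2862573476293778
  uniform_drop: false
tree_and_sampling:
  deterministic: true
  force_col_wise: true
  min_sum_hessian_in_leaf: 87.74013625036233
  feature_fraction: 0.25455318721130743
  other_rate: 0.09885757333923684
  min_data_per_group: 435
  max_cat_threshold: 1734
  cat_l2: 85.84302114069115
  feature_fraction_bynode: 0.375789890524636
  extra_trees: false
  max_bin: 387
computational:
  n_jobs: -1
  cat_smooth: 62.80892158399032
  top_k: 887
  cegb_tradeoff: 98.43099413468349
  scale_pos_weight: 4.6257547692635566
  sigmoid: 64.16478915867698
  verbose: -1
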