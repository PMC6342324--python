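# Demo pipeline: simulate a monoallelic population, test both count models,
# then simulate a clustered tissue section and estimate its seed size.
# Run with:  allelesim run --config examples/full_run.yaml
seed: 7
out_dir: allelesim_demo
stages:
  - simulate_counts:
      model: all_or_none
      n_cells: 500
      p_bl6: 0.5
      lam: 3.0
      fdr_bl6: 0.02
      fdr_jf1: 0.02
  - models:
      tests: [coin_flip, all_or_none]
      n_sims: 1000
      fdr_bl6: 0.02
      fdr_jf1: 0.02
  - simulate_tissue:
      n_cells: 1500
      seed_size: 4
  - spatial:
      grid_min: 4
      grid_max: 12
      n_sim: 150
  - simulate_spots:
      n_guide: 1500
  - colocalize:
      scan: true
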