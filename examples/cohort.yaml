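# Demonstration pipeline run at reduced scale (read-level emission is
# molecule-resolution and scales with patients x positions x depth; the
# consensus-level workflow in ctdnamon.workflows handles full cohorts).
seed: 1
simulate:
  n_patients: 8
  panel_positions: 300
  consensus_depth_target: 1200
  n_donors: 10
groom:
  duplex_only: false
errordb:
  alpha: 0.01
calls:
  min_vaf: 0.001
monitor:
  min_gene_freq: 0.10
stats:
  km_grid_months: [12, 24, 36]
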