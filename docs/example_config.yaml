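# ple-scout configuration: every pipeline default, overridable per key.
capture:
  element_free_k: 20
  flank_identity_threshold: 0.9
  junction_window: 50
  min_anchor: 200
classify:
  anchor_k: 12
  family_cut: 0.25
  group_cut: 0.45
  inclusion_fraction: 0.3333333333333333
  subfamily_cut: 0.1
forge:
  at_fraction: 0.7
  background: uniform
  boundary_slack_bp: 2
orf:
  intact_len_tolerance: 0.05
  min_aa: 300
  nrich_min_len: 100
  nrich_threshold: 0.25
  nrich_window: 50
  trunc_threshold_aa: 30
palindrome:
  max_mismatch: 2
  max_spacer: 4
  min_len: 10
  terminal_window: 5
promoter:
  inr_motif: TCACT
  max_spacing: 50
  rev_inr_motif: ACATT
  spacing: 20
  tata_motif: TATATATA
repeat:
  commit_run: 8
  max_mismatch_run: 5
  min_identity: 0.8
  min_unit: 50
  seed_k: 12
smallrna:
  max_mismatch: 1
  min_run: 3
  window: 100
tsd:
  max_len: 25
  max_mismatch: 0
  min_len: 4
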