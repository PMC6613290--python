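# Desk-scale two-site run. Every tunable design decision is a named option
# here; omitted keys fall back to the library defaults in docs/methods.md.
seed: 1
output_dir: vrisk_run
sites: [s1, s2]

profiles:
  s1:
    n_patients: 480
    notelen_log_mean: 5.0106   # ln 150: short synthetic documents
    notelen_log_sd: 0.45
    vocab_size: 800
    site_shift: 0.8
    signal_terms:
      - [aggressive, 2.0]
      - [angry, 2.0]
      - [threatening, 2.0]
      - [agitation, 2.0]
      - [emergency_medication, 2.0]
      - [seclusion, 2.0]
      - [irritated, 2.0]
      - [shouting, 2.0]
      - [restless, 2.0]
      - [refuses, 2.0]
      - [voluntary, -1.5]
      - [dejected, -1.5]
  s2:
    n_patients: 480
    notelen_log_mean: 5.0106
    notelen_log_sd: 0.45
    vocab_size: 800
    site_shift: 0.8
    signal_terms:
      - [aggressive, 2.0]
      - [angry, 2.0]
      - [threatening, 2.0]
      - [agitation, 2.0]
      - [emergency_medication, 2.0]
      - [seclusion, 2.0]
      - [irritated, 2.0]
      - [shouting, 2.0]
      - [restless, 2.0]
      - [refuses, 2.0]
      - [voluntary, -1.5]
      - [dejected, -1.5]

embedding:
  dimension: 48
  epochs: 12
  min_term_count: 3
  variant: distributed-bag-of-words

grid:
  - {cost: 1.0, kernel_width: scale}
  - {cost: 1.0, kernel_width: 0.01}
  - {cost: 10.0, kernel_width: scale}
  - {cost: 10.0, kernel_width: 0.01}

k_outer: 5
k_inner: 5
max_gap_days: 14
term_k: 1000
term_B: 1000
term_top_n: 20
alpha: 0.01
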