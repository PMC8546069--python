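# Default synthetic study design: ten cohorts (participants + 2
# facilitators each), six weekly sessions, 5-minute baselines.
# Pass to `grouplink run-all --config examples/default_study.yaml`.
n_cohorts: 10
cohort_sizes: [6, 6, 6, 6, 7, 7, 7, 7, 8, 8]
n_sessions: 6
session_lengths_min: [90, 90, 90, 90, 90, 60]
baseline_length_min: 5
n_facilitator_pool: 5
seed: 1
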