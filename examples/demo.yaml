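# Demo pipeline configuration: simulate a small cohort, fit the decision
# boundary on 70-s working-memory-analog sessions, then classify a fresh
# cohort of 180-s storytelling-analog sessions against it.
seed: 7
subjects: 12
channel: L3
bins: 16
load_low: 1.0
load_high: 2.0
fit_task_s: 70.0
eval_task_s: 180.0
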