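# Example pipeline configuration for `blinkclean pipeline --config ...`
# Flat key-value settings; unknown keys are rejected.
out_dir: blinkclean_run
seed: 20220211
recording_format: csv     # csv or edf
n_windows: 10000          # training-set size
epochs: 10
batch_size: 128
learning_rate: 0.001
test_duration: 60.0       # held-out recording length, seconds
n_components: 15          # ICA components
n_remove: 2               # ICA components to reject
highpass_cutoff: 1.0      # Hz
filter_order: 6
verbosity: INFO
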