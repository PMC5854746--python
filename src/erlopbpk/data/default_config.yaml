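# Default run configuration: the standard fasted patient on the study regimen.
scenario: standard
dose_mg: 100.0
interval_h: 24.0
n_doses: 1
duration_h: 24.0
output_dir: results
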