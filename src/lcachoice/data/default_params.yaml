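# Calibrated reference parameters (see scripts/calibrate.py, docs/methods.md)
dt: 0.05
tau_value: 3.093
tau_response: 1.709
tau_time_fast: 0.3
tau_time_slow: 2.7849
leak: 1.0
self_excitation: 0.52
lateral_inhibition: 0.75
w_time: 0.714
w_value: 1.0
sigmoid_gain: 4.2
sigmoid_center: 0.4
noise_sd: 0.003
threshold_low: 1.03
threshold_high: 1.14
time_compression: 0.2314
max_steps: 1200
drive_max: 1.0
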