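# Psi configuration for the random dot motion (RDM) coherence staircase.
# Intensity is motion coherence in [0, 1]; the task is effectively
# two-alternative, hence the 0.5 expected minimum.
intensity_range: [0.0, 1.0]
threshold_range: [0.0, 0.5]
slope_range: [0.01, 0.2]
intensity_precision: 0.01
threshold_precision: 0.01
slope_precision: 0.1
guess_rate: 0.05
step_type: lin
expected_minimum: 0.5
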