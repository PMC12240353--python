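# Psi configuration for the face affect discrimination (FAD) morph staircase.
# Intensity is the morph level 0-200 (0-100 % happy in 0.5 % steps); the
# outcome is the probability of a 'happy' response, so the lower asymptote
# is 0.
intensity_range: [0.0, 200.0]
threshold_range: [0.0, 200.0]
slope_range: [0.001, 50.0]
intensity_precision: 1.0
threshold_precision: 1.0
slope_precision: 1.0
guess_rate: 0.02
step_type: lin
expected_minimum: 0.0
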