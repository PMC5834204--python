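# skittles task configuration (flat schema; keys are TaskConfig field names)
# units: lengths/positions in cm, times in s, omega in rad/s,
#        sample_rate in Hz, angles handled downstream in degrees
ball_radius: 2.5
lever_length: 40.0
lever_pivot: [0.0, -150.0]
max_display_error: 40.0
miss_threshold: 2.5
name: i_shape
omega: 9.42477796076938
post_center: [0.0, 0.0]
post_radius: 25.0
sample_rate: 1000.0
success_threshold: 1.1
target_center: [13.68, 112.41]
target_radius: 2.5
tau: .inf
throw_direction: counterclockwise
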