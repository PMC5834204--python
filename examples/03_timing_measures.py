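"""Turn an arm trajectory into an error trajectory and timing measures.

Scoring every sample of a recorded (here: synthetic) arm trajectory as a
hypothetical release yields the error trajectory.  Its minimum marks the
ideal release; the distance in time between actual and ideal release is the
timing error, and the stretch of time the error stays below the success
threshold is the timing window — the tolerance the movement affords to
release-time noise.
"""

from skittles import (
    NoiseModel,
    analyze_throw,
    error_trajectory,
    generate_arm_trajectory,
    load_task,
    strategy_through_state,
    timing_measures_invariant,
)

config = load_task("j_shape")
# a sweep molded through a manifold state at 385 deg/s (clockwise task)
strategy = strategy_through_state(92.8, -385.0, 0.45, movement_time=0.5)
noise = NoiseModel(release_jitter_sd=15.0, amplitude_sd=1.5, duration_sd=20.0, seed=4)
traj = generate_arm_trajectory(strategy, noise, config)

result, measures = analyze_throw(traj, config)
et = error_trajectory(traj, config)
print(f"trajectory: {len(traj)} samples at {config.sample_rate:.0f} Hz, "
      f"release at sample {traj.release_index}")
print(f"throw error   : {result.error:.3f} cm ({result.category})")
print(f"timing error  : {measures.timing_error:.1f} ms "
      f"(ideal release at {measures.ideal_release_time * 1000:.0f} ms)")
print(f"timing window : {measures.timing_window:.1f} ms "
      f"({len(et.subthreshold_intervals)} sub-threshold segment(s))")

polar, cart = timing_measures_invariant(traj, config)
print(f"\ncoordinate check: polar vs Cartesian timing error "
      f"{polar.timing_error:.1f} == {cart.timing_error:.1f} ms, "
      f"window {polar.timing_window:.1f} == {cart.timing_window:.1f} ms")
print("Both measures are properties of the physical launches, so they do")
print("not depend on which execution variables parameterize the space.")
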