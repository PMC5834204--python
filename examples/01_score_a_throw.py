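"""Score single throws: from release state to flight to error.

A throw is fully determined by the lever angle and angular velocity at
release.  The ball then flies on a damped elliptic orbit around the centre
post; the throw error is the minimum distance between that orbit and the
target centre, and a throw counts as a hit when the error stays below the
1.1 cm success threshold without touching the post.
"""

from skittles import ReleaseState, lever_state_to_launch, load_task, score_throw

config = load_task("u_shape")
print(f"task: {config.name}, target at {config.target_center} cm, "
      f"{config.throw_direction} throws\n")

for angle, velocity in [(90.0, -380.0), (85.0, -390.0), (90.0, -150.0)]:
    state = ReleaseState(angle=angle, angular_velocity=velocity)
    launch = lever_state_to_launch(state, config)
    result = score_throw(state, config)
    print(f"release at {angle:5.1f} deg, {velocity:7.1f} deg/s  "
          f"-> launch speed {sum(v * v for v in launch.velocity) ** 0.5:6.1f} cm/s, "
          f"error {result.error:7.3f} cm, {result.category}"
          + ("  (hit the post)" if result.post_hit else ""))

print("\nThe error is the closest the ball comes to the target centre;")
print("below 1.1 cm the throw is a hit, above 2.5 cm it missed the target.")
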