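"""Search for strategies whose trajectories mold to the solution manifold.

Practice lengthens the timing window by shaping the arm trajectory to
overlap the solution manifold.  The calibration search looks for a
minimum-jerk sweep whose noiseless error trajectory stays sub-threshold for
a requested duration.  On the I-shape geometry the manifold is parallel to
the velocity axis, so no sweep can dwell in it longer than the time needed
to cross its angular band — the search reports that floor as unachievable.
"""

from skittles import calibrate_strategy_to_manifold, load_task

for name, target in [("box_shape", 40.0), ("i_shape", 150.0)]:
    config = load_task(name)
    res = calibrate_strategy_to_manifold(config, target_window_ms=target)
    verdict = "achieved" if res.achieved else "UNREACHABLE"
    print(f"{name}: target window {target:.0f} ms -> {verdict}, "
          f"best {res.achieved_window_ms:.0f} ms")
    print(f"  release state ({res.release_angle:.1f} deg, "
          f"{res.release_velocity:.0f} deg/s), movement time "
          f"{res.params.movement_time:.2f} s\n")

print("The box-shape manifold rewards slower, aligned sweeps; the I-shape")
print("window is pinned at the band-crossing time no matter the strategy.")
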