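"""Simulate a practice cohort and run the session-level statistics.

Ten synthetic subjects practice one task for several days (scaled down here
to keep the example quick).  Release jitter drops onto a plateau early
while trajectory alignment keeps improving, so the timing error levels off
while the timing window keeps growing — and by the last day the window, not
the timing error, dominates the standardized regression of performance
error.
"""

from skittles import load_task, simulate_learning_cohort

config = load_task("box_shape")
cohort = simulate_learning_cohort(
    config, n_subjects=8, days=4, throws_per_day=60, seed=11
)

print(f"task: {config.name}\n")
print(cohort.day_means().round(2)[
    ["success_rate", "median_error", "median_timing_error", "mean_timing_window"]
].to_string())

print("\nstandardized regressions (performance error on timing measures):")
for day, r in sorted(cohort.regressions.items()):
    print(f"  day {day}: beta1(timing error) = {r.beta1:+.2f}, "
          f"beta2(timing window) = {r.beta2:+.2f}, R^2 = {r.r_squared:.2f}")

print("\nTiming error drops sharply after day 1 and levels off, while the")
print("timing window keeps growing day after day.  At the full study scale")
print("(10 subjects, 6 days, 240 throws/day) the final-day regression is")
print("window-dominated, |beta2| > |beta1| — scripts/acceptance.py runs it.")
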