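"""Map the solution space of a task and extract its solution manifold.

The execution space is spanned by release angle and release speed.  Scoring
every grid cell colours the space into hits, near misses, misses and
invalid throws (post hits / huge errors); the set of hits is the solution
manifold — the redundant family of perfect throws this task affords.
"""

import numpy as np

from skittles import evaluate_grid, extract_manifold, load_task, velocity_sensitivity

for name in ("u_shape", "i_shape"):
    config = load_task(name)
    grid = evaluate_grid(config, resolution=(120, 120))
    counts = grid.category_counts()
    total = grid.error.size
    print(f"{name}: {counts['hit']} of {total} cells are solutions "
          f"({100 * counts['hit'] / total:.1f}%), {counts['invalid']} invalid")

    slices = [s for s in extract_manifold(grid) if s.velocity_intervals]
    angles = [s.angle for s in slices]
    widths = [s.total_width for s in slices]
    print(f"  manifold spans release angles {min(angles):.0f}-{max(angles):.0f} deg, "
          f"mean velocity tolerance {np.mean(widths):.0f} deg/s per angle")

    sens = velocity_sensitivity(grid)
    idx = [i for i, s in enumerate(extract_manifold(grid)) if s.velocity_intervals]
    print(f"  median error variation across velocity (CV): "
          f"{np.nanmedian(sens[idx]):.3f}\n")

print("The I-shape manifold runs parallel to the velocity axis: at a given")
print("release angle almost any speed works (hundreds of deg/s of tolerance,")
print("versus a few tens for the U-shape).")
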