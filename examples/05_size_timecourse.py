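"""HDL shrinkage over incubation time, with histogram smoothing.

As CETP transfers cholesteryl ester out of HDL, the particles shrink; the
generator scales the HDL diameter mean by the configured fractional decrease
at each time point.  The summary recovers the percent change, and diameter
histograms (0.5 nm bins) are smoothed with a 6th-degree polynomial.
"""

import numpy as np

from lipocount import (
    build_histogram,
    default_config,
    generate_timecourse,
    geometric_mean_diameter,
    smooth_histogram,
    summarize,
)

cfg = default_config(seed=3, n_particles=3000)
records = generate_timecourse(cfg)
summary = summarize(records)

print("mean HDL diameter over time (control arm):")
ctrl = summary[summary["condition"] == "control"]
for _, row in ctrl.iterrows():
    print(f"  t={row['time_min']:5.0f} min  n={row['n']:5d}  "
          f"{row['mean_diameter']:5.2f} +/- {row['sd_diameter']:.2f} nm  "
          f"({row['percent_change_from_t0']:+.1f}% vs t=0)")
print("configured decreases: 0% (0, 15 min), 17% (40 min), 21% (2 h), 30% (8 h)")

t0 = records[(records["condition"] == "control") & (records["time_min"] == 0)]
d = geometric_mean_diameter(t0["diameter_long"].to_numpy(),
                            t0["diameter_perp"].to_numpy())
hist = smooth_histogram(build_histogram(d, 0.5), degree=6)
peak = hist.midpoints[np.argmax(hist.smooth_values)]
print(f"t=0 histogram: {len(hist.counts)} half-nm bins, "
      f"smoothed curve peaks at {peak:.2f} nm (degree {hist.smooth_degree}, "
      f"RSS {hist.smooth_rss:.0f})")
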