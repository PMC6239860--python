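"""Check the closed-form visibility probability against Monte Carlo sampling.

Attachment points are drawn uniformly on the sphere; a rod protrusion is
counted visible when its tip projects beyond the sphere silhouette.  The
sampled fraction should sit within a few standard errors of
cos(arcsin(d / (d + 2 l))).
"""

import math

from lipocount import simulate_visible_fraction, visibility_probability

n = 10**6
for d in (10.0, 20.0, 30.0):
    p = visibility_probability(d, 8.0)
    est = simulate_visible_fraction(d, 8.0, n_samples=n, seed=int(d))
    se = math.sqrt(p * (1 - p) / n)
    print(f"d={d:4.0f} nm: analytic {p:.5f}, Monte Carlo {est:.5f} "
          f"(|diff| = {abs(est - p) / se:.2f} standard errors)")
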