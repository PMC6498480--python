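"""Designation probabilities upon reassessment, as a function of percent change.

For a single 30 mm solid lesion read by a different reader, tabulates the
probability that a hypothetical second assessment designates a response
(change <= -30%) or progression (>= +20%) for first-reading changes on a
grid — the sigmoid transition around the cut-offs is where trial results are
vulnerable to measurement variability.
"""

import numpy as np

from recistvar import (
    PosteriorDraws,
    Scenario,
    build_probability_table,
    default_variance_components,
)

posterior = PosteriorDraws(draws=[default_variance_components("long")], n_chains=1)
cs = [-1.0, -0.6, -0.45, -0.4, -0.35, -0.3, -0.25, -0.2, -0.1, 0.0,
      0.1, 0.15, 0.2, 0.25, 0.3, 0.5]
grid = [Scenario(n_solid=1, n_lymph=0, c=c, reader_mode="inter", baseline_mm=30)
        for c in cs]
table = build_probability_table(grid, posterior, n_iter=10, n_burdens=2000,
                                rng=np.random.default_rng(4))

print(f"{'change c':>9s} {'P(response)':>12s} {'P(progression)':>15s}")
for sc in grid:
    p_resp, p_prog = table.entries[sc.key]
    print(f"{sc.c:>+9.2f} {p_resp:>12.3f} {p_prog:>15.3f}")

print("\nAway from the cut-offs the designation is nearly certain; within a"
      " few percent of -30% (or +20%) a reassessment is close to a coin flip.")
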