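"""From a GPS track to used/available choice sets.

Computes the movement statistics that delimit availability (mean and SD of
the hourly movement rate), the availability radius c(a + 2b), builds one
choice set per fix (the used location plus five random points in the
buffer), and screens the continuous covariates for collinearity at
|r| <= 0.6.
"""

import numpy as np

from choicersf import (
    DesignCoding,
    LandscapeConfig,
    MovementConfig,
    availability_radius,
    build_choice_sets,
    generate_landscape,
    movement_stats,
    screen_collinearity,
    simulate_track,
)

# two strongly correlated covariates exercise the screen
corr = np.eye(4)
corr[0, 1] = corr[1, 0] = 0.85
grids = generate_landscape(
    LandscapeConfig(n_rows=64, n_cols=64, n_continuous=4, cross_correlation=corr),
    seed=3,
)
coding = DesignCoding.from_grids(grids)
beta = np.zeros(coding.n_columns)
beta[0] = 1.0
track = simulate_track(
    grids, beta, MovementConfig(step_radius=400), 400, (960, 960), seed=4
)

stats = movement_stats(track, nominal_interval=5.0)
radius = availability_radius(stats)
print(f"movement rate: a = {stats.a:.1f} m/hr, b = {stats.b:.1f} m/hr, c = {stats.c} hr")
print(f"availability radius c(a + 2b) = {radius:.0f} m")

data = build_choice_sets(track, grids, n_available=5, seed=5)
print(f"{data.n_sets} choice sets of {data.n_alternatives} alternatives, "
      f"{data.n_columns} design columns")

res = screen_collinearity(data, threshold=0.6)
print(f"screen retained: {res.retained}")
for col, r in res.dropped:
    print(f"screen dropped {col} (worst pairwise |r| = {r:.2f})")
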