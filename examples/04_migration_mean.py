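"""The shifting seasonal migration: mean function and a simulated track.

The north-south mean oscillates annually between a southern range at 0 and
a northern range that drifts from 8 toward 10 over the years; an OU walker
tracks it with a ~1-week reversion time.
"""

from movegp import migration_dataset, migration_mean

for t in (0.0, 0.25, 0.5, 1.0, 3.0, 100.0):
    print(f"  m_y({t:6.2f} yr) = {migration_mean(t)[1]:.3f}")
# integer years sit at the northern endpoint (8 rising toward 10),
# half-integer years at the southern endpoint (0).

traj, mean_fn = migration_dataset(n_years=3, fix_days=7, seed=11)
print(f"simulated {len(traj)} weekly fixes over 3 years")
err = traj.values[:, 1] - mean_fn(traj.times)[:, 1]
print(f"walker's north-south deviation from the route: sd = {err.std():.2f} "
      f"(stationary OU spread ~0.3 plus tracking lag)")
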