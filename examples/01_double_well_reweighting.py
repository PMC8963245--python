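"""Boosted sampling of a 1D double well, reweighted back to the exact PMF.

Runs the staged protocol (conventional stage for statistics, boosted
equilibration, frozen-parameter production) on a quartic double well with a
5 k_B T barrier, then recovers the canonical free-energy profile by
second-order cumulant reweighting and compares it with the exact
quadrature answer.
"""

import numpy as np

import pepgamd as pg

surface = pg.make_double_well(barrier_height=5.0, well_separation=2.0)
protocol = pg.ProtocolSpec(
    n_cmd_steps=5000, n_equil_steps=20_000, n_prod_steps=400_000,
    n_replicas=1, seed=1, sample_interval=10,
)
result = pg.run_gamd(surface, protocol, sigma_0=10.0)
params = result.params
print(f"boost parameters after equilibration: k0={params.k0:.3f}, "
      f"E={params.threshold_E:.3f}, sigma_dV={params.sigma_dv:.3f} (limit 10)")

traj = result.production[0]
profile = pg.reweight_profile(
    traj.coords[:, 0], traj.dv_total, bin_width=0.2, cutoff_frames=500,
    beta=1.0, bin_range=(-2.0, 2.0),
)
oracle = pg.analytic_pmf(surface, 0, beta=1.0, bins=profile.bin_edges[0])
mask = profile.included & oracle.included
err = np.abs(profile.f[mask] - oracle.f[mask]).max()

print("\n  x      F_reweighted   F_exact   frames")
for i in np.flatnonzero(mask):
    print(f"{profile.bin_centers[0][i]:6.2f}   {profile.f[i]:10.3f}"
          f" {oracle.f[i]:10.3f}   {int(profile.counts[i]):7d}")
print(f"\nmax |F - F_exact| over included bins: {err:.3f} k_B T")
print("The reweighted profile reproduces the exact double-well PMF (two")
print("0 k_B T minima at x = +-1, a ~5 k_B T barrier at x = 0) to within")
print("statistical noise; bins with fewer than 500 frames are excluded.")
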