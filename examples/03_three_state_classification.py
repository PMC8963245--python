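"""State identification on a three-basin activation landscape.

The landscape plants basins at activation-coordinate values 8.6, 11.1 and
15.3 (mimicking inactive / intermediate / active wells of a GPCR
activation distance, in angstrom-like units).  A boosted run is reweighted
along that coordinate; local minima of the profile are located and
labelled by the default state bands.
"""

import numpy as np

import pepgamd as pg

landscape = pg.make_three_state_landscape(
    minima_positions=[(8.6, 10.0), (11.1, 10.0), (15.3, 10.0)],
    depths=[5.0, 4.4, 4.6],
    widths=[0.9, 0.9, 0.9],
)
protocol = pg.ProtocolSpec(
    n_cmd_steps=5000, n_equil_steps=20_000, n_prod_steps=400_000,
    n_replicas=1, seed=4, sample_interval=10,
)
result = pg.run_gamd(landscape, protocol, sigma_0=10.0)
traj = result.production[0]

profile = pg.reweight_profile(
    traj.coords[:, 0], traj.dv_total, bin_width=0.5, cutoff_frames=500,
    beta=1.0, bin_range=(5.0, 20.0),
)
minima = pg.find_minima(profile, depth_threshold=3.0)
labelled = pg.classify_states(minima, pg.default_state_bands())

oracle = pg.analytic_pmf(landscape, 0, beta=1.0, bins=profile.bin_edges[0],
                         n_quad=501)
centers = profile.bin_centers[0]
print("state          position   F (k_B T)   F_exact")
for state, pos, f in labelled:
    i = int(np.argmin(np.abs(centers - pos)))
    print(f"{state:<12} {pos:9.2f} {f:10.3f} {oracle.f[i]:10.3f}")

print("\nEach planted basin shows up as a low-energy state in the correct")
print("band (Inactive < 10, Intermediate 10-13, Active >= 13), with free")
print("energies matching the exact marginal PMF of the landscape.")
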