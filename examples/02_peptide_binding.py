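"""Dual-boost sampling of repetitive peptide binding and unbinding.

Builds the bead peptide-receptor system, runs conventional dynamics and a
dual-boost run at matched production length, and counts binding <->
unbinding transitions of the funnel pair (peptide bead 0 vs the receptor
pocket apex).
"""

import numpy as np

import pepgamd as pg

system = pg.make_toy_peptide_system(n_peptide_beads=4, seed=1)
n_steps = 30_000

gamd = pg.run_pep_gamd(
    system,
    pg.ProtocolSpec(n_cmd_steps=2000, n_equil_steps=6000, n_prod_steps=n_steps,
                    n_replicas=1, seed=7, sample_interval=10),
    sigma_0_L=10.0, sigma_0_D=10.0,
)
print("essential-peptide boost:", gamd.params.peptide.summary())
print("rest-of-system boost:   ", gamd.params.rest.summary())

cmd = pg.run_cmd(system, pg.ProtocolSpec(n_prod_steps=n_steps, seed=7,
                                         sample_interval=10))

for name, traj in (("conventional", cmd), ("dual-boost", gamd.production[0])):
    d = np.linalg.norm(traj.coords[:, 0, :] - system.receptor_coords[0], axis=1)
    n_trans = pg.count_binding_transitions(d, bound_below=1.2, unbound_above=2.5)
    frac_bound = float(np.mean(d < 1.2))
    print(f"{name:>12}: {n_trans:3d} transitions, "
          f"bound fraction {frac_bound:.2f}, "
          f"distance range [{d.min():.2f}, {d.max():.2f}]")

print("\nThe dual boost lowers the effective binding barrier so the peptide")
print("repeatedly dissociates and rebinds within the same number of steps,")
print("while conventional dynamics stays trapped in the bound pose.")
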