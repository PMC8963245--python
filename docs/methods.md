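# Methods

## The model

`pepgamd` implements dual-boost Gaussian-accelerated sampling for
peptide–receptor systems at a scale where exact answers exist.  The method
adds a harmonic boost to the potential energy whenever it falls below a
threshold *E*:

    V*(r) = V(r) + ΔV(r),    ΔV(r) = ½ k (E − V(r))²  for V(r) < E, else 0.

Two principles constrain (*E*, *k*): the boost must preserve the relative
order of potential values (so the biased surface has the same minima) and
must shrink energy differences (so barriers are lowered).  Together they
bracket the threshold, `Vmax ≤ E ≤ Vmin + 1/k`, with `k = k0/(Vmax − Vmin)`
and `0 < k0 ≤ 1`.  A third principle keeps reweighting accurate: the
standard deviation of the boost, `σ_ΔV = k (E − Vavg) σ_V`, must stay below
a user limit `σ0` (default 10 k_B T).  With *E* at its lower bound
(`E = Vmax`, the default),

    k0 = min(1, (σ0/σ_V) · (Vmax − Vmin)/(Vmax − Vavg)),

and with *E* at its upper bound (`E = Vmin + 1/k`),

    k0″ = (1 − σ0/σ_V) · (Vmax − Vmin)/(Vavg − Vmin),

used when 0 < k0″ ≤ 1 and otherwise falling back to the lower-bound
formula (the implementation reports which branch fired).

For peptide binding, the *essential peptide energy* is boosted separately:

    V_L = V_LL,b + V_LL,nb + V_PL,nb + V_LE,nb

(peptide bonded, intra-peptide nonbonded, peptide–receptor nonbonded,
peptide–environment nonbonded), with an independent second boost on the
remainder V_D of the system energy.  The per-frame total boost
ΔV = ΔV_L + ΔV_D drives reweighting.

## Reweighting

A boosted run samples the biased density p*(A) along a reaction coordinate
A.  Per bin j, the canonical density is p(A_j) ∝ p*(A_j)·⟨e^{βΔV}⟩_j, with
the ensemble-averaged factor approximated by the cumulant expansion
truncated at second order: exp(βC1 + β²C2/2), C1 the per-bin mean of ΔV and
C2 its per-bin *population* variance.  In energy units,

    F(A_j) = F*(A_j) − C1,j − (β/2)·C2,j + Fc.

The truncation is exact for Gaussian boost distributions; the
`anharmonicity` diagnostic γ = ln√(2πe·σ²) − H[ΔV] (entropy deficit
relative to a matched Gaussian, histogram entropy with Scott's-rule bins)
quantifies departures.  Conventions: per-bin cumulants (never global); bins
or clusters with fewer than `cutoff_frames` (default 500) frames are
excluded, never interpolated; the minimum over included bins anchors
Fc so the reported global minimum is exactly 0; default bin width is 1
coordinate unit (ångström-scale for activation distances), with 1×1 square
bins in 2D.  The exponent is assembled in log space; overflow never enters
the free-energy arithmetic.

The constant Fc is unknowable from a single run, so only free-energy
*differences* are meaningful; anchoring at 0 makes profiles comparable
across runs.

## Integration and the staged protocol

Dynamics is Langevin with BAOAB splitting at fixed time step — the best
configurational accuracy per step among the standard splittings at desk
scale; there is no barostat, constraint algorithm or long-range
electrostatics (out of scope for the toy systems).  Boosted forces are
physical forces scaled per term by `1 − k(E − V)`, which lies in [0, 1]
inside the statistics bracket (forces are damped, never inverted).

The staged protocol mirrors production practice, scaled to steps:

1. **Conventional stage** (`n_cmd_steps`): no boost; collects Vmax, Vmin
   and Welford running mean/variance (population convention) of each
   boosted term.  These samples are included in the statistics by default
   (`include_cmd_statistics=False` disables this).
2. **Equilibration** (`n_equil_steps`): boost on; (k0, k, E) refreshed from
   the running statistics every `update_interval` steps (default 50).
3. **Production** (`n_prod_steps` × `n_replicas`, default 3 replicas):
   parameters frozen — this keeps the reweighting identity well-defined.
   Frames whose energy exceeds the frozen Vmax are *not* an error: the
   frozen boost simply evaluates them (ΔV = 0 above E); the engine counts
   such frames per replica (`vmax_exceeded`).

Randomness: one master seed feeds a counter-based (Philox) generator;
production replica *r* uses seed `master + r`, so each replica is
independently reproducible.  `σ0 = 0` cleanly degenerates to conventional
dynamics (k0 = 0, ΔV ≡ 0).

Time step: the stiffest toy interaction is the peptide bond
(κ = 100, ω = 10 in reduced units), giving a stability bound dt ≪ 2/ω = 0.2;
the default dt = 0.02 leaves a 10× margin and keeps the BAOAB
configurational bias at the 10⁻⁴ level.

## Toy systems and what they emulate

All toy systems use reduced units: k_B T = 1 at the reference temperature,
lengths in bead diameters.  The configuration layer also supports a
kcal/mol mode (β from a temperature in kelvin, default 310 K) for files
produced externally.

- **Double well** (quartic, default barrier 5 k_B T): the minimal system
  with a rare transition; its PMF is known in closed form.
- **Three-state landscape**: inverted Gaussians at activation-coordinate
  values 8.6 / 11.1 / 15.3 with depths 5.0 / 4.4 / 4.6 k_B T and width 0.9,
  inside a quadratic confining wall.  The positions mimic reported
  inactive / intermediate / active wells of a GPCR activation distance, but
  they are labels of convenience, not physical claims.  Depths and widths
  were chosen so that all three wells survive as clear local minima of the
  *marginal* (x-projected) PMF with ≥ 0.5 k_B T barrier margins — a shallow
  middle well disappears when the orthogonal coordinate is integrated out.
- **Toy peptide system**: a 2-to-10-bead harmonic chain in 2D near a fixed
  3-bead receptor pocket.  One attractive soft-core pair (peptide bead 0 ↔
  pocket apex, depth 8 k_B T) forms a binding funnel; every other
  nonbonded contact is soft-core repulsive (`V = ε s⁶` with
  `s = σ²/(r² + σ²/2)`, finite at contact so large time steps stay
  stable).  Four mobile environment beads give the rest-term V_D genuine
  fluctuations; a circular wall (radius 4) guarantees rebinding.  The wall
  force on peptide beads is classified as an environment field (V_LE,nb),
  on environment beads as V_rest; the constant receptor-internal energy
  sits in V_rest so the five-term decomposition sums exactly to V_total.
  Receptor beads are strictly fixed (infinite mass).

What the toys do *not* emulate: explicit solvent and electrostatics,
force-field realism, conformational entropy of real peptides, and membrane
environments.  Passing tests therefore demonstrate the correctness of the
boost/reweighting/analysis machinery, not the physics of any real
receptor.

### Synthetic weighted samples

`synth_weighted_samples` draws (coordinate, boost) pairs whose reweighted
profile must reproduce a stated target PMF.  For a boost with conditional
mean g(A) and Gaussian spread sd, the biased density that reweights back to
the target is p*(A) ∝ e^{−βF(A)}·e^{−βg(A)} (the sd² term is a constant
that cancels); coordinates come from inverse-CDF sampling on a dense grid
and boosts from the model conditional on the coordinate, clipped at zero
(keep mean ≫ sd so clipping is negligible).

### The quadrature oracle

`analytic_pmf` computes F(A) = −(1/β) ln ∫ e^{−βV} δ(A(r) − A) dr, with the
δ realized as histogram binning on the same grid the estimator uses, so
oracle and estimate share binning bias.  When the coordinate is an axis
projection (the usual case), the quadrature is *bin-aligned*: each output
bin is subdivided into midpoint cells, making per-bin masses true composite
integrals.  A generic callable coordinate falls back to a dense domain-grid
histogram, which carries a per-bin mass jitter of order
(grid spacing / bin width) — acceptable for 0.5 k_B T comparisons, not for
10⁻³ ones.

## Analysis conventions

- **Minima**: local minima over included bins (4-neighborhood in 2D);
  excluded bins and borders count as higher neighbors; equal-valued
  plateaus are flood-filled and resolve to the lowest flat bin index;
  minima more than `depth_threshold` (default 3 k_B T) above the global
  minimum are dropped.
- **State bands**: ordered, contiguous, closed-open intervals on the
  activation coordinate; defaults Inactive [0, 10), Intermediate [10, 13),
  Active [13, ∞), chosen to separate wells near 8–9 / 10.7–11.1 / 13–15.3;
  fully configurable, never hard-coded in the analysis logic.  A salt-bridge
  convenience flag marks charge-center distances < 5 as formed.
- **Clustering**: average-linkage agglomerative on the dense pairwise
  matrix of RMSD after optimal rigid superposition (Kabsch, unweighted
  coordinates, reflection-corrected).  Average linkage and unweighted RMSD
  are the common defaults of trajectory-clustering tools; mass weighting is
  deliberately not applied.  Clusters are re-labelled by descending
  population (ties broken by smallest member frame index, so results are
  deterministic for a given frame order); each cluster is represented by
  its medoid.  Per-cluster free energies treat clusters as bins of the
  reweighting estimator, with the same 500-frame cutoff and zero-anchoring.
  The dense O(n²) matrix is intended for ≤ ~10⁴ frames after striding;
  `stride` is exposed in the config and CLI.
- **Binding transitions** are counted by a two-threshold hysteresis
  automaton (bound < 1.2, unbound > 2.5 bead diameters for the default toy
  system) to suppress boundary chatter.

## Numerical choices

- Population (not sample) variance throughout, matching the reweighting
  toolkit convention.
- Per-bin accumulation uses `np.bincount`, not `np.histogram(weights=…)`:
  the latter's block-cumsum path cancels tiny tail masses to exactly zero.
- Bin edges are anchored at integer multiples of the bin width (or an
  explicit range), so profiles from different runs share grids.
- k0 selection defers (boost inactive) until statistics can support it
  (≥ 2 samples, positive spread); degenerate statistics passed explicitly
  to the k0 formulas raise a dedicated error.
- Energy guard at |V| > 10¹⁰ aborts integration with the failing step
  number.

## Problem sizes in the shipped tests

The test suite and acceptance script choose desk-scale sizes that the
statistics comfortably support: 2×10⁶ production steps for the double-well
PMF comparison (max error vs quadrature ≲ 0.15 k_B T, asserted ≤ 0.5),
1×10⁶ for the three-state recovery, 10 seed pairs × 3×10⁴ matched steps
for the transition-count comparison, and 10⁶ draws for the
Gaussian-truncation and anharmonicity checks.

## Known limitations

- 2D bead mechanics; no solvent, electrostatics, or force fields.
- Cumulant expansion strictly to second order; no exponential-average or
  Maclaurin variants, no WHAM/MBAR.
- The generic-coordinate oracle path has the documented binning jitter.
- Cluster free energies inherit the binning caveat that clusters are
  treated as unordered bins; no error bars are attached.
- External trajectory ingestion is limited to the documented XYZ + TSV
  dialects (plus the 3-column legacy weights export).
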