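"""Analytic model potentials, a bead peptide-receptor system, and synthetic
weighted samples.

Everything downstream of the sampling engine (reweighting, free-energy
profiles, state classification, clustering) is validated against these
systems because their Boltzmann statistics can be computed exactly by dense
numerical quadrature.

Units
-----
All toy systems use reduced units with ``k_B T = 1`` at the reference
temperature, so energies are in units of k_B T, ``beta = 1`` and lengths are
in bead diameters.  The reweighting layer accepts an explicit ``beta`` for
physical-unit (kcal/mol) inputs; nothing here depends on the choice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import (
    InvalidParameterError,
    NumericalOverflowError,
)
from .reweighting import FreeEnergyProfile

__all__ = [
    "PotentialSurface",
    "ToyPeptideSystem",
    "SyntheticWeightedSample",
    "ConstantBoost",
    "GaussianBoost",
    "StateDependentBoost",
    "make_double_well",
    "make_three_state_landscape",
    "make_toy_peptide_system",
    "analytic_pmf",
    "synth_weighted_samples",
]


# --------------------------------------------------------------------------
# Analytic surfaces
# --------------------------------------------------------------------------

@dataclass
class PotentialSurface:
    """A low-dimensional analytic potential with gradient.

    ``energy`` and ``gradient`` are vectorized: points may be a single
    configuration of shape ``(d,)`` or a batch of shape ``(N, d)``.

    Attributes
    ----------
    dimensionality : int
        1 or 2.
    energy : callable
        Maps point(s) to energy value(s) in k_B T.
    gradient : callable
        Maps point(s) to the energy gradient, same leading shape as input.
    domain_bounds : tuple of (lo, hi)
        Closed interval per dimension within which the energy is finite and
        sampling is meaningful.
    name : str
    metadata : dict
        Analytically known features (minimum positions, barrier height, ...).
    """

    dimensionality: int
    energy: Callable[[np.ndarray], np.ndarray]
    gradient: Callable[[np.ndarray], np.ndarray]
    domain_bounds: tuple[tuple[float, float], ...]
    name: str
    metadata: dict = field(default_factory=dict)

    def grid(self, n_per_dim: int = 801) -> np.ndarray:
        """Dense midpoint quadrature grid over ``domain_bounds``, shape
        ``(N, d)``.  Cell midpoints avoid placing points exactly on typical
        histogram bin edges, which would bias tie-breaking."""
        axes = [
            lo + (np.arange(n_per_dim) + 0.5) * (hi - lo) / n_per_dim
            for lo, hi in self.domain_bounds
        ]
        if self.dimensionality == 1:
            return axes[0][:, None]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=-1)

    def grid_cell_volume(self, n_per_dim: int = 801) -> float:
        vol = 1.0
        for lo, hi in self.domain_bounds:
            vol *= (hi - lo) / n_per_dim
        return vol


def make_double_well(barrier_height: float, well_separation: float) -> PotentialSurface:
    """1D quartic double well ``V(x) = h ((x/a)^2 - 1)^2`` with ``a = s/2``.

    The two minima sit at ``x = -a, +a`` with ``V = 0`` and the barrier at
    ``x = 0`` with ``V = h`` (``h`` = ``barrier_height`` in k_B T).
    """
    if barrier_height <= 0:
        raise InvalidParameterError("barrier_height must be > 0")
    if well_separation <= 0:
        raise InvalidParameterError("well_separation must be > 0")
    h = float(barrier_height)
    a = float(well_separation) / 2.0

    def energy(p):
        p = np.asarray(p, dtype=float)
        x = p[..., 0]
        return h * ((x / a) ** 2 - 1.0) ** 2

    def gradient(p):
        p = np.asarray(p, dtype=float)
        x = p[..., 0]
        g = 4.0 * h * x * ((x / a) ** 2 - 1.0) / a**2
        return g[..., None]

    return PotentialSurface(
        dimensionality=1,
        energy=energy,
        gradient=gradient,
        domain_bounds=((-2.5 * a, 2.5 * a),),
        name="double_well",
        metadata={
            "minima": [(-a,), (a,)],
            "barrier_position": (0.0,),
            "barrier_height": h,
        },
    )


def make_three_state_landscape(
    minima_positions: Sequence[Sequence[float]],
    depths: Sequence[float],
    widths: Sequence[float],
) -> PotentialSurface:
    """2D sum-of-inverted-Gaussians landscape with a confining quadratic wall.

    ``V(p) = -sum_i d_i exp(-|p - m_i|^2 / (2 w_i^2)) + wall(p)``.

    Emulates a multi-basin activation landscape: placing the first
    coordinate of the minima at e.g. 8.6 / 11.1 / 15.3 mimics the inactive /
    intermediate / active wells of a GPCR activation distance, but the
    landscape itself is synthetic.

    Preconditions: at least two minima, positive depths, and pairwise
    separation greater than twice the largest width (so each requested
    minimum survives as a local minimum of the sum).
    """
    m = np.asarray(minima_positions, dtype=float)
    d = np.asarray(depths, dtype=float)
    w = np.asarray(widths, dtype=float)
    if m.ndim != 2 or m.shape[1] != 2:
        raise InvalidParameterError("minima_positions must be a list of 2D points")
    if len(m) < 2:
        raise InvalidParameterError("need at least two minima")
    if len(d) != len(m) or len(w) != len(m):
        raise InvalidParameterError("depths and widths must match minima count")
    if np.any(d <= 0) or np.any(w <= 0):
        raise InvalidParameterError("depths and widths must be > 0")
    wmax = float(w.max())
    for i in range(len(m)):
        for j in range(i + 1, len(m)):
            sep = float(np.linalg.norm(m[i] - m[j]))
            if sep <= 2.0 * wmax:
                raise InvalidParameterError(
                    f"minima {i} and {j} separated by {sep:.3f} <= 2 x max width "
                    f"{2 * wmax:.3f}: wells would merge"
                )

    lo = m.min(axis=0) - 3.0 * wmax
    hi = m.max(axis=0) + 3.0 * wmax
    k_wall = 2.0

    def energy(p):
        p = np.asarray(p, dtype=float)
        diff = p[..., None, :] - m  # (..., n_min, 2)
        r2 = np.sum(diff**2, axis=-1)
        v = -np.sum(d * np.exp(-r2 / (2.0 * w**2)), axis=-1)
        under = np.clip(lo - p, 0.0, None)
        over = np.clip(p - hi, 0.0, None)
        v = v + k_wall * np.sum(under**2 + over**2, axis=-1)
        return v

    def gradient(p):
        p = np.asarray(p, dtype=float)
        diff = p[..., None, :] - m
        r2 = np.sum(diff**2, axis=-1)
        weights = d * np.exp(-r2 / (2.0 * w**2)) / w**2  # (..., n_min)
        g = np.sum(weights[..., None] * diff, axis=-2)
        under = np.clip(lo - p, 0.0, None)
        over = np.clip(p - hi, 0.0, None)
        g = g + 2.0 * k_wall * (over - under)
        return g

    return PotentialSurface(
        dimensionality=2,
        energy=energy,
        gradient=gradient,
        domain_bounds=tuple((float(a), float(b)) for a, b in zip(lo - 2.0, hi + 2.0)),
        name="three_state_landscape",
        metadata={
            "minima": [tuple(pt) for pt in m],
            "depths": list(map(float, d)),
            "widths": list(map(float, w)),
            "wall_box": (tuple(map(float, lo)), tuple(map(float, hi))),
        },
    )


# --------------------------------------------------------------------------
# Toy peptide-receptor system
# --------------------------------------------------------------------------

# Soft-core pair shapes.  With s = sigma^2 / (r^2 + c), c = 0.5 sigma^2:
#   repulsive:   V = eps * s^6               (finite cap 64*eps at r = 0)
#   attractive:  V = eps * (s^6 - 2 s^3)     (minimum -eps at r = sigma/sqrt(2))
# Both decay to zero at large separation; soft cores keep Langevin stable at
# the working time step.
_SOFTNESS = 0.5


def _pair_energy_force_coeff(r2, eps, sigma, attractive):
    """Return (energy, coeff) with force on i = coeff * (r_i - r_j)."""
    c = _SOFTNESS * sigma**2
    s = sigma**2 / (r2 + c)
    if attractive:
        e = eps * (s**6 - 2.0 * s**3)
        coeff = 12.0 * eps * s**4 * (s**3 - 1.0) / sigma**2
    else:
        e = eps * s**6
        coeff = 12.0 * eps * s**7 / sigma**2
    return e, coeff


@dataclass
class ToyPeptideSystem:
    """Bead-chain peptide near a fixed 3-bead receptor pocket, in 2D.

    The total potential energy is decomposed exactly as

        V_total = V_LL,b + V_LL,nb + V_PL,nb + V_LE,nb + V_rest

    where the first four terms form the essential peptide energy ``V_L``
    (peptide bonds, intra-peptide nonbonded, peptide-receptor nonbonded,
    peptide-environment nonbonded -- the confining wall acting on peptide
    beads counts as an environment field) and ``V_rest = V_D`` collects
    everything not involving the peptide (environment-internal,
    environment-receptor, environment wall, and the constant
    receptor-internal energy).

    Receptor beads are fixed (infinite mass): dynamics only moves the
    peptide and environment beads, in that order, in the "mobile" array.
    """

    peptide_coords: np.ndarray      # (n_pep, 2) initial positions
    receptor_coords: np.ndarray     # (3, 2) fixed
    environment_coords: np.ndarray  # (n_env, 2) initial positions
    bond_rest_length: float
    bond_stiffness: float
    eps_repulsive: float
    sigma_repulsive: float
    eps_binding: float
    sigma_binding: float
    wall_center: np.ndarray
    wall_radius: float
    wall_stiffness: float
    temperature: float = 1.0        # k_B T in reduced units
    seed: int = 0

    COMPONENT_NAMES = ("V_LL_b", "V_LL_nb", "V_PL_nb", "V_LE_nb", "V_rest")

    def __post_init__(self):
        self.peptide_coords = np.array(self.peptide_coords, dtype=float)
        self.receptor_coords = np.array(self.receptor_coords, dtype=float)
        self.environment_coords = np.array(self.environment_coords, dtype=float)
        self.n_peptide = len(self.peptide_coords)
        self.n_environment = len(self.environment_coords)
        self.n_mobile = self.n_peptide + self.n_environment
        # Pair lists (indices into the full array: mobile beads first, then
        # the fixed receptor), grouped by decomposition term.
        npep, nenv = self.n_peptide, self.n_environment
        rec0 = self.n_mobile  # index of first receptor bead in full array
        self._bonds = np.array([(i, i + 1) for i in range(npep - 1)], dtype=int).reshape(-1, 2)
        self._pp = np.array(
            [(i, j) for i in range(npep) for j in range(i + 2, npep)], dtype=int
        ).reshape(-1, 2)
        self._pr = np.array(
            [(i, rec0 + r) for i in range(npep) for r in range(3)], dtype=int
        ).reshape(-1, 2)
        # Binding pair: peptide bead 0 with receptor bead 0 (the pocket apex).
        self._pr_attractive = np.array(
            [i for i, (p, r) in enumerate(self._pr) if p == 0 and r == rec0], dtype=int
        )
        self._pe = np.array(
            [(i, npep + e) for i in range(npep) for e in range(nenv)], dtype=int
        ).reshape(-1, 2)
        self._ee = np.array(
            [(npep + i, npep + j) for i in range(nenv) for j in range(i + 1, nenv)],
            dtype=int,
        ).reshape(-1, 2)
        self._er = np.array(
            [(npep + e, rec0 + r) for e in range(nenv) for r in range(3)], dtype=int
        ).reshape(-1, 2)
        # Receptor-internal energy: constant, no force on mobile beads.
        vrr = 0.0
        for i in range(3):
            for j in range(i + 1, 3):
                r2 = float(np.sum((self.receptor_coords[i] - self.receptor_coords[j]) ** 2))
                e, _ = _pair_energy_force_coeff(
                    r2, self.eps_repulsive, self.sigma_repulsive, False
                )
                vrr += e
        self._v_receptor_internal = vrr
        self._build_fast_tables()

    # Flattened pair tables and incidence matrices so one vectorized pass
    # per step yields all energies and split forces.  Category ids:
    # 0 = V_LL_nb, 1 = V_PL_nb, 2 = V_LE_nb, 3/4 = V_rest (ee, er).
    def _build_fast_tables(self):
        groups = [self._pp, self._pr, self._pe, self._ee, self._er]
        pairs = np.concatenate(
            [g.reshape(-1, 2) for g in groups], axis=0
        ).astype(int)
        cats = np.concatenate(
            [np.full(len(g), c, dtype=int) for c, g in enumerate(groups)]
        ).astype(int)
        P = len(pairs)
        eps = np.full(P, self.eps_repulsive)
        sig = np.full(P, self.sigma_repulsive)
        attr = np.zeros(P, dtype=bool)
        # locate the binding pair (category 1 block, local indices in _pr)
        off = len(self._pp)
        for k in self._pr_attractive:
            eps[off + k] = self.eps_binding
            sig[off + k] = self.sigma_binding
            attr[off + k] = True
        onehot = np.zeros((5, P))
        onehot[cats, np.arange(P)] = 1.0
        s_L = np.zeros((self.n_mobile, P))
        s_D = np.zeros((self.n_mobile, P))
        for p in range(P):
            tgt = s_L if cats[p] <= 2 else s_D
            i, j = pairs[p]
            if i < self.n_mobile:
                tgt[i, p] += 1.0
            if j < self.n_mobile:
                tgt[j, p] -= 1.0
        self._nb_pairs = pairs
        self._nb_eps, self._nb_sig, self._nb_attr = eps, sig, attr
        self._nb_onehot, self._nb_sL, self._nb_sD = onehot, s_L, s_D
        B = len(self._bonds)
        s_b = np.zeros((self.n_mobile, B))
        for p, (i, j) in enumerate(self._bonds):
            s_b[i, p] += 1.0
            s_b[j, p] -= 1.0
        self._bond_incidence = s_b

    # -- geometry ----------------------------------------------------------

    @property
    def masses(self) -> np.ndarray:
        return np.ones(self.n_mobile)

    @property
    def elements(self) -> list[str]:
        """Bead classes as element symbols: peptide C, environment O, receptor N."""
        return (
            ["C"] * self.n_peptide + ["O"] * self.n_environment + ["N"] * 3
        )

    def initial_mobile_coords(self) -> np.ndarray:
        return np.concatenate([self.peptide_coords, self.environment_coords], axis=0)

    def full_coords(self, mobile: np.ndarray) -> np.ndarray:
        return np.concatenate([mobile, self.receptor_coords], axis=0)

    def binding_distance(self, mobile: np.ndarray) -> float:
        """Distance between peptide bead 0 and receptor bead 0 (the funnel pair)."""
        return float(np.linalg.norm(mobile[0] - self.receptor_coords[0]))

    # -- energies and forces ----------------------------------------------

    def _wall(self, coords):
        """Harmonic wall beyond wall_radius; returns (energy, force array)."""
        diff = coords - self.wall_center
        r = np.linalg.norm(diff, axis=1)
        excess = np.clip(r - self.wall_radius, 0.0, None)
        e = 0.5 * self.wall_stiffness * np.sum(excess**2)
        f = np.zeros_like(coords)
        mask = excess > 0
        if np.any(mask):
            f[mask] = -(self.wall_stiffness * excess[mask] / r[mask])[:, None] * diff[mask]
        return float(e), f

    def energy_components(self, mobile: np.ndarray | None = None) -> dict[str, float]:
        """The five-term energy decomposition at the given mobile coordinates."""
        comp, _, _ = self._energy_forces_detail(
            self.initial_mobile_coords() if mobile is None else np.asarray(mobile, float)
        )
        return comp

    def total_energy(self, mobile: np.ndarray | None = None) -> float:
        return float(sum(self.energy_components(mobile).values()))

    def _energy_forces_detail(self, mobile):
        full = self.full_coords(mobile)
        npep = self.n_peptide

        # Bonds (V_LL,b)
        diff_b = full[self._bonds[:, 0]] - full[self._bonds[:, 1]]
        r = np.sqrt(np.sum(diff_b**2, axis=1))
        dr = r - self.bond_rest_length
        v_b = float(0.5 * self.bond_stiffness * np.sum(dr**2))
        f_L = self._bond_incidence @ ((-self.bond_stiffness * dr / r)[:, None] * diff_b)

        # All nonbonded pairs in one vectorized pass
        pairs = self._nb_pairs
        diff = full[pairs[:, 0]] - full[pairs[:, 1]]
        r2 = np.sum(diff**2, axis=1)
        sig2 = self._nb_sig**2
        s = sig2 / (r2 + _SOFTNESS * sig2)
        s3 = s * s * s
        s6 = s3 * s3
        e = np.where(self._nb_attr, self._nb_eps * (s6 - 2.0 * s3), self._nb_eps * s6)
        coeff = np.where(
            self._nb_attr,
            12.0 * self._nb_eps * s * s3 * (s3 - 1.0) / sig2,
            12.0 * self._nb_eps * s * s6 / sig2,
        )
        cat_e = self._nb_onehot @ e  # (5,): pp, pr, pe, ee, er
        fv = coeff[:, None] * diff
        f_L = f_L + self._nb_sL @ fv
        f_D = self._nb_sD @ fv

        # Walls: peptide wall is an environment field -> V_LE,nb; environment
        # wall -> V_rest.
        e_wp, f_wp = self._wall(mobile[:npep])
        e_we, f_we = self._wall(mobile[npep:])
        f_L[:npep] += f_wp
        f_D[npep:] += f_we

        comp = {
            "V_LL_b": v_b,
            "V_LL_nb": float(cat_e[0]),
            "V_PL_nb": float(cat_e[1]),
            "V_LE_nb": float(cat_e[2]) + e_wp,
            "V_rest": float(cat_e[3] + cat_e[4]) + e_we + self._v_receptor_internal,
        }
        return comp, f_L, f_D

    def energy_forces(self, mobile: np.ndarray):
        """(V_L, V_D, F_L, F_D) for the dual-boost integrator.

        ``F_L`` is minus the gradient of the essential peptide energy with
        respect to all mobile beads (environment beads feel peptide-
        environment forces through V_L), ``F_D`` likewise for the rest term.
        """
        comp, f_L, f_D = self._energy_forces_detail(mobile)
        v_L = comp["V_LL_b"] + comp["V_LL_nb"] + comp["V_PL_nb"] + comp["V_LE_nb"]
        return v_L, comp["V_rest"], f_L, f_D


def make_toy_peptide_system(n_peptide_beads: int, seed: int) -> ToyPeptideSystem:
    """Deterministically build the toy peptide-receptor system.

    A chain of ``n_peptide_beads`` harmonic-bonded beads starts bound in a
    fixed 3-bead receptor pocket (peptide bead 0 pairs attractively with the
    pocket apex at the origin; all other nonbonded contacts are soft-core
    repulsive).  A few mobile environment beads and a circular confining
    wall provide the "rest" degrees of freedom and guarantee rebinding after
    dissociation, emulating the repetitive binding/unbinding the dual-boost
    method is designed to sample.
    """
    if not (2 <= n_peptide_beads <= 10):
        raise InvalidParameterError("n_peptide_beads must be in [2, 10]")
    rng = np.random.Generator(np.random.Philox(key=seed & 0x7FFFFFFF))
    r0 = 0.7
    # Receptor pocket: apex at origin, two flanking beads forming a notch.
    receptor = np.array([[0.0, 0.0], [-0.9, 0.9], [-0.9, -0.9]])
    # Peptide starts bound: bead 0 at the attractive minimum distance from
    # the apex, chain extending outward with a small seeded jitter.
    sigma_bind = 1.0
    r_min = sigma_bind * math.sqrt(1.0 - _SOFTNESS)
    pep = np.zeros((n_peptide_beads, 2))
    pep[0] = [r_min, 0.0]
    for i in range(1, n_peptide_beads):
        pep[i] = pep[i - 1] + [r0, 0.0]
    pep += 0.05 * rng.standard_normal(pep.shape)
    # Environment beads scattered away from the pocket, inside the wall.
    n_env = 4
    env = np.zeros((n_env, 2))
    for e in range(n_env):
        ang = 2.0 * math.pi * (e + 0.5) / n_env + 0.1 * rng.standard_normal()
        rad = 2.6 + 0.3 * rng.standard_normal()
        env[e] = [rad * math.cos(ang), rad * math.sin(ang)]
    return ToyPeptideSystem(
        peptide_coords=pep,
        receptor_coords=receptor,
        environment_coords=env,
        bond_rest_length=r0,
        bond_stiffness=100.0,
        eps_repulsive=1.0,
        sigma_repulsive=0.8,
        eps_binding=8.0,
        sigma_binding=sigma_bind,
        wall_center=np.zeros(2),
        wall_radius=4.0,
        wall_stiffness=5.0,
        temperature=1.0,
        seed=int(seed),
    )


# --------------------------------------------------------------------------
# Quadrature PMF oracle
# --------------------------------------------------------------------------

def analytic_pmf(
    surface: PotentialSurface,
    coordinate_fn,
    beta: float,
    bins: np.ndarray,
    n_quad: int = 801,
) -> FreeEnergyProfile:
    """Exact (quadrature) PMF of a scalar coordinate on an analytic surface.

    Computes ``F(A) = -(1/beta) ln Int exp(-beta V(r)) delta(A(r) - A) dr``
    by dense quadrature over the surface domain, realizing the delta
    function as histogram binning on ``bins`` (the same binning rule the
    reweighting estimator uses, so oracle and estimate share discretization
    bias).  The profile is anchored so the global minimum is 0.

    Parameters
    ----------
    coordinate_fn : int or callable
        An integer selects an axis projection (preferred: the quadrature
        grid is then aligned to the bin edges, so per-bin masses are true
        composite-midpoint integrals); a callable ``points -> values`` uses
        a generic domain grid histogram, whose per-bin mass carries a small
        grid-alignment jitter of order (grid spacing / bin width).
    bins : array of bin edges for the coordinate.
    n_quad : quadrature points per dimension (>= 200 required).
    """
    if n_quad < 200:
        raise InvalidParameterError("need >= 200 quadrature points per dimension")
    edges = np.asarray(bins, dtype=float)
    nb = len(edges) - 1

    if callable(coordinate_fn):
        pts = surface.grid(n_quad)
        v = np.asarray(surface.energy(pts), dtype=float)
        if not np.all(np.isfinite(v)):
            raise NumericalOverflowError("surface energy non-finite on quadrature grid")
        w = np.exp(-beta * (v - v.min()))
        if not np.all(np.isfinite(w)) or w.sum() <= 0:
            raise NumericalOverflowError("unnormalizable Boltzmann weight")
        a = np.asarray(coordinate_fn(pts), dtype=float).reshape(-1)
        # per-bin accumulation via bincount: unlike the cumsum path inside
        # np.histogram(weights=...), this keeps tiny tail masses exact
        k = np.searchsorted(edges, a, side="right") - 1
        k[a == edges[-1]] = nb - 1
        valid = (k >= 0) & (k < nb)
        mass = np.bincount(k[valid], weights=w[valid], minlength=nb)
        counts = np.bincount(k[valid], minlength=nb)
    else:
        axis = int(coordinate_fn)
        if not 0 <= axis < surface.dimensionality:
            raise InvalidParameterError(f"axis {axis} out of range")
        # bin-aligned composite midpoint rule along the profiled axis
        m = max(8, int(np.ceil(n_quad / nb)))
        sub = (np.arange(m) + 0.5) / m
        widths = np.diff(edges)
        xs = edges[:-1, None] + widths[:, None] * sub[None, :]  # (nb, m)
        if surface.dimensionality == 1:
            pts = xs.reshape(-1, 1)
            v = np.asarray(surface.energy(pts), dtype=float)
            if not np.all(np.isfinite(v)):
                raise NumericalOverflowError("surface energy non-finite on grid")
            w = np.exp(-beta * (v - v.min())).reshape(nb, m)
            mass = w.sum(axis=1) * (widths / m)
            counts = np.full(nb, m)
        else:
            other = 1 - axis
            lo, hi = surface.domain_bounds[other]
            ys = lo + (np.arange(n_quad) + 0.5) * (hi - lo) / n_quad
            pts = np.empty((nb * m, n_quad, 2))
            pts[..., axis] = xs.reshape(-1)[:, None]
            pts[..., other] = ys[None, :]
            v = np.asarray(surface.energy(pts.reshape(-1, 2)), dtype=float)
            if not np.all(np.isfinite(v)):
                raise NumericalOverflowError("surface energy non-finite on grid")
            w = np.exp(-beta * (v - v.min())).reshape(nb, m, n_quad)
            mass = w.sum(axis=(1, 2)) * (widths / m) * ((hi - lo) / n_quad)
            counts = np.full(nb, m * n_quad)
    p = mass / mass.sum()
    include = p > 0
    f = np.full(len(p), np.nan)
    with np.errstate(divide="ignore"):
        f[include] = -np.log(p[include]) / beta
    f -= np.nanmin(f)
    return FreeEnergyProfile(
        bin_edges=(edges,),
        f=f,
        f_star=f.copy(),
        c1=np.zeros(len(p)),
        c2=np.zeros(len(p)),
        counts=counts.astype(float),
        beta=float(beta),
        cutoff_frames=0,
    )


# --------------------------------------------------------------------------
# Synthetic weighted samples
# --------------------------------------------------------------------------

@dataclass
class ConstantBoost:
    """Every frame carries the same boost ``value`` (>= 0)."""
    value: float

    def mean_at(self, a):
        return np.full_like(np.asarray(a, dtype=float), self.value)

    def draw(self, rng, a):
        return np.full(len(a), float(self.value))


@dataclass
class GaussianBoost:
    """Boost values i.i.d. Normal(mean, sd), independent of the coordinate.

    Draws are clipped at zero to honour the non-negativity of a boost
    potential; keep ``mean >> sd`` so clipping is negligible.
    """
    mean: float
    sd: float

    def mean_at(self, a):
        return np.full_like(np.asarray(a, dtype=float), self.mean)

    def draw(self, rng, a):
        return np.clip(rng.normal(self.mean, self.sd, size=len(a)), 0.0, None)


@dataclass
class StateDependentBoost:
    """Boost mean varies with the coordinate: ``dV ~ Normal(mean_fn(A), sd)``."""
    mean_fn: Callable[[np.ndarray], np.ndarray]
    sd: float

    def mean_at(self, a):
        return np.asarray(self.mean_fn(np.asarray(a, dtype=float)), dtype=float)

    def draw(self, rng, a):
        mu = self.mean_at(a)
        return np.clip(mu + self.sd * rng.standard_normal(len(a)), 0.0, None)


@dataclass
class SyntheticWeightedSample:
    """Coordinate values paired with boost potentials, built so that
    cumulant reweighting must reproduce ``generating_pmf``."""

    coordinate_values: np.ndarray
    boost_values: np.ndarray
    generating_pmf: Callable[[np.ndarray], np.ndarray]
    seed: int

    def __post_init__(self):
        self.coordinate_values = np.asarray(self.coordinate_values, dtype=float)
        self.boost_values = np.asarray(self.boost_values, dtype=float)
        if len(self.coordinate_values) != len(self.boost_values):
            raise InvalidParameterError("coordinate and boost series must have equal length")
        if np.any(self.boost_values < 0):
            raise InvalidParameterError("boost values must be non-negative")


def synth_weighted_samples(
    target_pmf: Callable[[np.ndarray], np.ndarray],
    boost_model,
    n: int,
    seed: int,
    *,
    domain: tuple[float, float],
    beta: float = 1.0,
    grid_points: int = 4097,
) -> SyntheticWeightedSample:
    """Draw (coordinate, boost) pairs whose reweighted PMF is ``target_pmf``.

    Construction.  Let g(A) be the boost-model mean at coordinate A and sd
    its (coordinate-independent) spread.  For Gaussian boost noise the
    per-bin reweighting factor is E[e^{beta dV} | A] =
    exp(beta g(A) + beta^2 sd^2 / 2), so the *biased* density that recovers
    the target after reweighting is

        p*(A)  proportional to  exp(-beta F(A)) * exp(-beta g(A))

    (the sd^2 term is constant and cancels in the normalization).
    Coordinates are drawn from p* by inverse-CDF sampling on a dense grid;
    boost values are then drawn from the model conditional on the sampled
    coordinate.  For constant or coordinate-independent models g is constant
    and p* reduces to the target density itself.
    """
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    sd = getattr(boost_model, "sd", 0.0)
    if sd < 0:
        raise InvalidParameterError("boost sd must be >= 0")
    rng = np.random.Generator(np.random.Philox(key=seed & 0x7FFFFFFF))
    grid = np.linspace(domain[0], domain[1], grid_points)
    logp = -beta * np.asarray(target_pmf(grid), dtype=float)
    logp = logp - beta * boost_model.mean_at(grid)
    logp -= logp.max()
    pdf = np.exp(logp)
    # midpoint-rule CDF on the grid
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (pdf[1:] + pdf[:-1]))])
    cdf /= cdf[-1]
    u = rng.random(n)
    coords = np.interp(u, cdf, grid)
    boosts = boost_model.draw(rng, coords)
    return SyntheticWeightedSample(
        coordinate_values=coords,
        boost_values=boosts,
        generating_pmf=target_pmf,
        seed=int(seed),
    )
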