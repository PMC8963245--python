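"""Reaction coordinates, low-energy-state identification, and structural
clustering with per-cluster reweighted free energies.

The analysis conventions mirror standard GPCR activation work: a scalar
"activation" distance (e.g. the intracellular TM3-TM6 separation) indexes
receptor state, low-energy wells of a reweighted profile are located and
labelled Inactive / Intermediate / Active by configurable coordinate bands,
and representative conformations come from average-linkage agglomerative
clustering on pairwise RMSD after optimal rigid-body superposition, ranked
by population with a medoid representative per cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import (
    EmptyProfileError,
    InputShapeError,
    InvalidParameterError,
    SelectionError,
    SuperpositionDegeneracyError,
)
from .reweighting import FreeEnergyProfile

__all__ = [
    "DistanceSpec",
    "StateBands",
    "ClusterResult",
    "distance_series",
    "rmsd_after_superposition",
    "hierarchical_cluster",
    "cluster_free_energies",
    "find_minima",
    "classify_states",
    "default_state_bands",
    "count_binding_transitions",
    "salt_bridge_formed",
]


# --------------------------------------------------------------------------
# Reaction coordinates
# --------------------------------------------------------------------------

@dataclass
class DistanceSpec:
    """A labelled inter-selection distance.

    ``mode='single'`` requires one index per selection (e.g. one charge
    center per residue); ``mode='centroid'`` measures between selection
    centroids.
    """

    label: str
    selection_a: tuple[int, ...]
    selection_b: tuple[int, ...]
    mode: str = "single"

    def __post_init__(self):
        self.selection_a = tuple(self.selection_a)
        self.selection_b = tuple(self.selection_b)
        if not self.selection_a or not self.selection_b:
            raise InvalidParameterError("selections must be non-empty")
        if set(self.selection_a) & set(self.selection_b):
            raise InvalidParameterError("selections must be disjoint")
        if self.mode not in ("single", "centroid"):
            raise InvalidParameterError("mode must be 'single' or 'centroid'")
        if self.mode == "single" and (len(self.selection_a) != 1 or len(self.selection_b) != 1):
            raise InvalidParameterError("'single' mode takes exactly one index per side")


def distance_series(frames, spec: DistanceSpec) -> np.ndarray:
    """Per-frame Euclidean distance between the two selection points."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise InputShapeError("frames must have shape (n_frames, n_particles, d)")
    n_particles = frames.shape[1]
    bad = [i for i in spec.selection_a + spec.selection_b if not 0 <= i < n_particles]
    if bad:
        raise SelectionError(
            f"selection index {bad[0]} out of range for frames with "
            f"{n_particles} particles (frame 0)"
        )
    a = frames[:, list(spec.selection_a)].mean(axis=1)
    b = frames[:, list(spec.selection_b)].mean(axis=1)
    return np.linalg.norm(a - b, axis=-1)


# --------------------------------------------------------------------------
# RMSD and clustering
# --------------------------------------------------------------------------

def _kabsch_rmsd_centered(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD after optimal rotation of centered point sets a, b (k, d)."""
    h = a.T @ b
    u, s, vt = np.linalg.svd(h)
    if np.linalg.det(u @ vt) < 0:
        s = s.copy()
        s[-1] *= -1.0
    k = a.shape[0]
    msd = (np.sum(a**2) + np.sum(b**2) - 2.0 * np.sum(s)) / k
    return float(np.sqrt(max(msd, 0.0)))


def rmsd_after_superposition(frame, reference, index_subset=None) -> float:
    """Root-mean-square deviation after least-squares rigid superposition.

    Rotation + translation are optimized (Kabsch algorithm, with the
    reflection corrected via the determinant sign).  Unweighted
    coordinates.  Requires at least 3 non-collinear points.
    """
    frame = np.asarray(frame, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if index_subset is not None:
        idx = list(index_subset)
        frame = frame[idx]
        reference = reference[idx]
    if frame.shape != reference.shape:
        raise InputShapeError("frame and reference shapes differ")
    if frame.shape[0] < 3:
        raise SuperpositionDegeneracyError("need at least 3 points")
    a = frame - frame.mean(axis=0)
    b = reference - reference.mean(axis=0)
    for pts in (a, b):
        sv = np.linalg.svd(pts, compute_uv=False)
        if sv[1] <= 1e-10 * max(sv[0], 1.0):
            raise SuperpositionDegeneracyError("points are (near-)collinear")
    return _kabsch_rmsd_centered(a, b)


def _pairwise_rmsd_condensed(frames: np.ndarray) -> np.ndarray:
    """Condensed pairwise superposition-RMSD matrix, batched over pairs."""
    x = frames - frames.mean(axis=1, keepdims=True)
    n, k, _ = x.shape
    ii, jj = np.triu_indices(n, 1)
    h = np.einsum("pki,pkj->pij", x[ii], x[jj])
    u, s, vt = np.linalg.svd(h)
    det = np.linalg.det(u @ vt)
    s[:, -1] *= np.sign(det)
    sq = np.sum(x**2, axis=(1, 2))
    msd = (sq[ii] + sq[jj] - 2.0 * s.sum(axis=1)) / k
    return np.sqrt(np.clip(msd, 0.0, None))


@dataclass
class ClusterResult:
    """Partition of frames into population-ranked structural clusters.

    Cluster ids are 1-based; cluster 1 is the most populated ("top-ranked").
    ``delta_f`` is filled by :func:`cluster_free_energies` (NaN = excluded
    by the frame cutoff).
    """

    assignments: np.ndarray
    representatives: np.ndarray
    populations: np.ndarray
    delta_f: np.ndarray | None = None
    linkage: str = "average"
    reference_rmsd: np.ndarray | None = field(default=None)

    @property
    def n_clusters(self) -> int:
        return len(self.populations)


def hierarchical_cluster(frames, reference=None, n_clusters: int = 10) -> ClusterResult:
    """Average-linkage agglomerative clustering on pairwise superposition RMSD.

    The dendrogram is cut at ``n_clusters``; clusters are re-labelled by
    descending population (ties broken by the smallest member frame index,
    so the result is deterministic for a given frame order) and each
    cluster is represented by its medoid (minimal mean RMSD to members).
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3:
        raise InputShapeError("frames must have shape (n_frames, n_particles, d)")
    n = len(frames)
    if n_clusters < 1 or n_clusters > n:
        raise InvalidParameterError(
            f"n_clusters must be in [1, {n}] (got {n_clusters})"
        )
    condensed = _pairwise_rmsd_condensed(frames)
    if n_clusters == n:
        raw = np.arange(1, n + 1)
    else:
        z = linkage(condensed, method="average")
        raw = fcluster(z, t=n_clusters, criterion="maxclust")
    dmat = squareform(condensed)

    labels = np.unique(raw)
    pops = {lab: int(np.sum(raw == lab)) for lab in labels}
    firsts = {lab: int(np.argmax(raw == lab)) for lab in labels}
    order = sorted(labels, key=lambda lab: (-pops[lab], firsts[lab]))
    remap = {lab: i + 1 for i, lab in enumerate(order)}
    assignments = np.array([remap[lab] for lab in raw], dtype=int)

    representatives = np.zeros(len(order), dtype=int)
    populations = np.zeros(len(order), dtype=int)
    for cid in range(1, len(order) + 1):
        members = np.flatnonzero(assignments == cid)
        populations[cid - 1] = len(members)
        sub = dmat[np.ix_(members, members)]
        representatives[cid - 1] = members[int(np.argmin(sub.mean(axis=1)))]

    ref_rmsd = None
    if reference is not None:
        reference = np.asarray(reference, dtype=float)
        ref_rmsd = np.array(
            [rmsd_after_superposition(frames[r], reference) for r in representatives]
        )
    return ClusterResult(
        assignments=assignments,
        representatives=representatives,
        populations=populations,
        linkage="average",
        reference_rmsd=ref_rmsd,
    )


def cluster_free_energies(
    result: ClusterResult,
    dv,
    beta: float,
    cutoff_frames: int = 500,
) -> ClusterResult:
    """Reweighted free energy per structural cluster (clusters as bins).

    Each cluster with population >= ``cutoff_frames`` gets
    dF = -(1/beta) ln(n_i / N) - C1_i - (beta/2) C2_i, anchored so the
    minimum included value is 0; smaller clusters are marked excluded (NaN).
    """
    dv = np.asarray(dv, dtype=float).ravel()
    if len(dv) != len(result.assignments):
        raise InputShapeError("dv length must equal the clustered frame count")
    n_total = len(dv)
    delta_f = np.full(result.n_clusters, np.nan)
    for cid in range(1, result.n_clusters + 1):
        members = result.assignments == cid
        n_i = int(members.sum())
        if n_i < max(int(cutoff_frames), 1):
            continue
        vals = dv[members]
        c1 = float(vals.mean())
        c2 = float(vals.var())
        delta_f[cid - 1] = -np.log(n_i / n_total) / beta - c1 - 0.5 * beta * c2
    if not np.any(np.isfinite(delta_f)):
        raise EmptyProfileError("no cluster reaches the frame cutoff")
    delta_f -= np.nanmin(delta_f)
    return replace(result, delta_f=delta_f)


# --------------------------------------------------------------------------
# Minima and state taxonomy
# --------------------------------------------------------------------------

def find_minima(profile: FreeEnergyProfile, depth_threshold: float = 3.0):
    """Local minima of a profile within ``depth_threshold`` of the global one.

    Neighborhood: the two adjacent bins in 1D, the 4-neighborhood in 2D.
    Excluded bins and grid borders count as "higher" neighbors.  Plateau
    ties resolve to the lowest flat bin index.  Returns a list of
    ``(position, f_value)`` sorted by free energy; ``position`` is a float
    (1D) or an (x, y) tuple (2D) of bin centers.
    """
    f = np.asarray(profile.f, dtype=float)
    centers = profile.bin_centers
    if not np.any(np.isfinite(f)):
        raise EmptyProfileError("profile has no included bins")
    fmin = np.nanmin(f)

    if profile.ndim == 1:
        grid = f[:, None]
    else:
        grid = f
    nx, ny = grid.shape[0], grid.shape[1]
    offsets = ((-1, 0), (1, 0), (0, -1), (0, 1))
    visited = np.zeros((nx, ny), dtype=bool)
    minima = []
    for i in range(nx):
        for j in range(ny):
            if visited[i, j] or not np.isfinite(grid[i, j]):
                continue
            # flood-fill the connected equal-valued plateau containing (i, j)
            v = grid[i, j]
            stack, plateau = [(i, j)], []
            visited[i, j] = True
            is_min = True
            while stack:
                a, b = stack.pop()
                plateau.append((a, b))
                for da, db in offsets:
                    c, e = a + da, b + db
                    if not (0 <= c < nx and 0 <= e < ny):
                        continue
                    w = grid[c, e]
                    if not np.isfinite(w):
                        continue
                    if w == v:
                        if not visited[c, e]:
                            visited[c, e] = True
                            stack.append((c, e))
                    elif w < v:
                        is_min = False
            if is_min and v - fmin <= depth_threshold:
                a, b = min(plateau)  # plateau tie -> lowest flat index
                if profile.ndim == 1:
                    minima.append((float(centers[0][a]), float(v)))
                else:
                    minima.append(((float(centers[0][a]), float(centers[1][b])), float(v)))
    minima.sort(key=lambda m: m[1])
    return minima


@dataclass
class StateBands:
    """Ordered, contiguous closed-open intervals labelling an activation
    coordinate (e.g. Inactive [0, 10), Intermediate [10, 13), Active
    [13, inf) on a TM3-TM6-like distance)."""

    bands: tuple[tuple[str, float, float], ...]

    def __post_init__(self):
        bands = tuple((str(n), float(lo), float(hi)) for n, lo, hi in self.bands)
        if not bands:
            raise InvalidParameterError("need at least one band")
        for name, lo, hi in bands:
            if not lo < hi:
                raise InvalidParameterError(f"band {name!r} has empty interval")
        for (_, _, hi_prev), (name, lo, _) in zip(bands, bands[1:]):
            if lo != hi_prev:
                raise InvalidParameterError(
                    f"bands must be contiguous; gap/overlap before {name!r}"
                )
        self.bands = bands

    def classify(self, x: float) -> str:
        for name, lo, hi in self.bands:
            if lo <= x < hi:
                return name
        return "unassigned"


def default_state_bands() -> StateBands:
    """Default activation-coordinate taxonomy separating reported wells
    near ~8-9 (inactive), ~10.7-11.1 (intermediate) and ~13-15.3 (active)."""
    return StateBands(
        bands=(
            ("Inactive", 0.0, 10.0),
            ("Intermediate", 10.0, 13.0),
            ("Active", 13.0, float("inf")),
        )
    )


def classify_states(minima: Sequence, bands: StateBands):
    """Label each (position, f) minimum by the band containing its
    activation coordinate (first coordinate for 2D positions)."""
    out = []
    for position, f_value in minima:
        x = position[0] if isinstance(position, (tuple, list, np.ndarray)) else position
        out.append((bands.classify(float(x)), position, f_value))
    return out


# --------------------------------------------------------------------------
# Convenience indicators
# --------------------------------------------------------------------------

def salt_bridge_formed(distance, threshold: float = 5.0) -> np.ndarray:
    """Charge-center contact flag: formed when the distance is below the
    threshold (reported contacts form at ~3.3-5 and break at ~6.5-8.3)."""
    return np.asarray(distance, dtype=float) < threshold


def count_binding_transitions(
    distances, bound_below: float, unbound_above: float
) -> int:
    """Count binding <-> unbinding events along a distance series.

    A two-threshold (hysteresis) automaton suppresses chatter: the state
    flips to bound only below ``bound_below`` and to unbound only above
    ``unbound_above``.  Every flip counts as one transition; the initial
    state is set by the first frame that crosses either threshold.
    """
    if not bound_below < unbound_above:
        raise InvalidParameterError("bound_below must be < unbound_above")
    d = np.asarray(distances, dtype=float)
    state = None
    n = 0
    for x in d:
        if x < bound_below:
            if state == "unbound":
                n += 1
            state = "bound"
        elif x > unbound_above:
            if state == "bound":
                n += 1
            state = "unbound"
    return n
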