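"""Unit tests for reaction coordinates, superposition RMSD, clustering,
minima finding and state classification."""

import numpy as np
import pytest

import pepgamd as pg
from pepgamd.errors import (
    InvalidParameterError,
    SelectionError,
    SuperpositionDegeneracyError,
)


class TestDistanceSeries:
    def test_simple_cases(self):
        frames = np.array(
            [
                [[0.0, 0.0, 0.0], [3.0, 4.0, 0.0]],
                [[1.0, 1.0, 1.0], [1.0, 1.0, 1.0]],
            ]
        )
        spec = pg.DistanceSpec("d", (0,), (1,))
        d = pg.distance_series(frames, spec)
        assert d[0] == pytest.approx(5.0)  # 3-4-5 triangle
        assert d[1] == pytest.approx(0.0)  # coincident points

    def test_centroid_mode(self):
        frames = np.array([[[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [3.0, 0.0, 0.0]]])
        spec = pg.DistanceSpec("d", (0,), (1, 2), mode="centroid")
        assert pg.distance_series(frames, spec)[0] == pytest.approx(2.0)

    def test_out_of_range_selection(self):
        frames = np.zeros((2, 3, 2))
        with pytest.raises(SelectionError):
            pg.distance_series(frames, pg.DistanceSpec("d", (0,), (5,)))

    def test_overlapping_selections_rejected(self):
        with pytest.raises(InvalidParameterError):
            pg.DistanceSpec("d", (0, 1), (1, 2), mode="centroid")


class TestRmsd:
    def test_identity_is_zero(self, rng):
        x = rng.standard_normal((6, 3))
        assert pg.rmsd_after_superposition(x, x) == pytest.approx(0.0, abs=1e-12)

    def test_rigid_transform_invariance(self, rng):
        x = rng.standard_normal((8, 3))
        theta = 0.7
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        y = x @ rot.T + np.array([3.0, -1.0, 2.0])
        assert pg.rmsd_after_superposition(y, x) == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_in_arguments(self, rng):
        a = rng.standard_normal((5, 3))
        b = rng.standard_normal((5, 3))
        assert pg.rmsd_after_superposition(a, b) == pytest.approx(
            pg.rmsd_after_superposition(b, a), abs=1e-9
        )

    def test_matches_dense_rotation_grid_oracle(self):
        """2D case: brute-force minimization over a dense rotation grid."""
        rng = np.random.default_rng(8)
        a = rng.standard_normal((4, 2))
        b = a + 0.3 * rng.standard_normal((4, 2))
        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)
        best = np.inf
        for th in np.linspace(0, 2 * np.pi, 200_000, endpoint=False):
            rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
            best = min(best, np.sqrt(np.mean(np.sum((ac @ rot.T - bc) ** 2, axis=1))))
        assert pg.rmsd_after_superposition(a, b) == pytest.approx(best, abs=1e-3)

    def test_collinear_points_rejected(self):
        line = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        with pytest.raises(SuperpositionDegeneracyError):
            pg.rmsd_after_superposition(line, line)


def _planted_conformers(n_per=20, jitter=0.02, seed=0):
    """Frames drawn from 3 well-separated rigid conformers (+ noise),
    returned with ground-truth labels."""
    rng = np.random.default_rng(seed)
    base = rng.standard_normal((3, 6, 3)) * 2.0
    frames, labels = [], []
    for c in range(3):
        for _ in range(n_per):
            theta = rng.uniform(0, 2 * np.pi)
            rot = np.array(
                [
                    [np.cos(theta), -np.sin(theta), 0],
                    [np.sin(theta), np.cos(theta), 0],
                    [0, 0, 1],
                ]
            )
            frames.append(base[c] @ rot.T + rng.uniform(-5, 5, 3)
                          + jitter * rng.standard_normal((6, 3)))
            labels.append(c)
    return np.array(frames), np.array(labels)


class TestHierarchicalCluster:
    def test_recovers_planted_partition(self):
        frames, labels = _planted_conformers()
        res = pg.hierarchical_cluster(frames, n_clusters=3)
        # same partition: assignments constant within each planted group,
        # distinct across groups
        for c in range(3):
            assert len(set(res.assignments[labels == c])) == 1
        assert len(set(res.assignments)) == 3

    def test_partition_property_and_ranking(self):
        frames, _ = _planted_conformers(n_per=15)
        res = pg.hierarchical_cluster(frames, n_clusters=3)
        assert res.populations.sum() == len(frames)
        assert np.all(np.diff(res.populations) <= 0)  # descending populations
        for cid in range(1, res.n_clusters + 1):
            rep = res.representatives[cid - 1]
            assert res.assignments[rep] == cid  # medoid belongs to its cluster

    def test_singletons_when_n_clusters_equals_frames(self):
        frames, _ = _planted_conformers(n_per=3)
        res = pg.hierarchical_cluster(frames, n_clusters=len(frames))
        assert np.all(res.populations == 1)

    def test_duplication_doubles_populations(self):
        frames, _ = _planted_conformers(n_per=8)
        res1 = pg.hierarchical_cluster(frames, n_clusters=3)
        res2 = pg.hierarchical_cluster(
            np.concatenate([frames, frames]), n_clusters=3
        )
        assert sorted(res2.populations) == sorted(2 * res1.populations)

    def test_too_many_clusters_rejected(self):
        frames, _ = _planted_conformers(n_per=2)
        with pytest.raises(InvalidParameterError):
            pg.hierarchical_cluster(frames, n_clusters=100)


class TestClusterFreeEnergies:
    def test_zero_boost_equals_population_ratio(self):
        frames, labels = _planted_conformers(n_per=20)
        # unbalance the populations
        keep = np.concatenate(
            [np.flatnonzero(labels == 0), np.flatnonzero(labels == 1)[:10],
             np.flatnonzero(labels == 2)[:5]]
        )
        frames = frames[keep]
        res = pg.hierarchical_cluster(frames, n_clusters=3)
        res = pg.cluster_free_energies(res, np.zeros(len(frames)), beta=1.0,
                                       cutoff_frames=1)
        pops = res.populations
        expected = -np.log(pops / pops.max())
        assert np.allclose(res.delta_f, expected, atol=1e-9)

    def test_constant_boost_closed_form(self):
        """Two clusters with constant boosts c1, c2: dF difference is
        -(1/beta)[ln(pop2/pop1) + beta (c2 - c1)]."""
        frames, labels = _planted_conformers(n_per=12)
        keep = labels < 2
        frames, labels = frames[keep], labels[keep]
        res = pg.hierarchical_cluster(frames, n_clusters=2)
        ca, cb = 1.5, 3.0
        dv = np.where(res.assignments == 1, ca, cb)
        out = pg.cluster_free_energies(res, dv, beta=1.0, cutoff_frames=1)
        p1, p2 = out.populations[0], out.populations[1]
        expected_diff = -(np.log(p2 / p1) + (cb - ca))
        assert (out.delta_f[1] - out.delta_f[0]) == pytest.approx(
            expected_diff, abs=1e-9
        )

    def test_single_qualifying_cluster_anchored_to_zero(self):
        frames, _ = _planted_conformers(n_per=10)
        res = pg.hierarchical_cluster(frames, n_clusters=3)
        out = pg.cluster_free_energies(
            res, np.zeros(len(frames)), beta=1.0,
            cutoff_frames=int(res.populations[0]),
        )
        finite = np.isfinite(out.delta_f)
        assert finite.sum() >= 1
        assert out.delta_f[finite].min() == 0.0


class TestFindMinimaAndStates:
    def _profile(self, f_values, start=0.0, width=1.0):
        f = np.asarray(f_values, dtype=float)
        edges = start + width * np.arange(len(f) + 1)
        return pg.FreeEnergyProfile(
            bin_edges=(edges,), f=f - np.nanmin(f), f_star=f.copy(),
            c1=np.zeros(len(f)), c2=np.zeros(len(f)),
            counts=np.full(len(f), 1000.0), beta=1.0, cutoff_frames=0,
        )

    def test_single_well(self):
        prof = self._profile([3.0, 1.0, 0.0, 1.0, 3.0])
        minima = pg.find_minima(prof, 3.0)
        assert len(minima) == 1
        assert minima[0][1] == 0.0

    def test_depth_threshold_zero_keeps_only_global(self):
        prof = self._profile([0.0, 2.0, 1.0, 2.0, 0.5])
        minima = pg.find_minima(prof, 0.0)
        assert [m[1] for m in minima] == [0.0]

    def test_plateau_resolves_to_lowest_bin(self):
        prof = self._profile([2.0, 1.0, 1.0, 2.0, 0.0, 3.0])
        minima = pg.find_minima(prof, 5.0)
        positions = sorted(p for p, _ in minima)
        assert positions == [1.5, 4.5]  # plateau keeps its first bin center

    def test_descending_plateau_edge_is_not_minimum(self):
        prof = self._profile([0.0, 1.0, 1.0, 2.0])
        minima = pg.find_minima(prof, 5.0)
        assert len(minima) == 1 and minima[0][0] == 0.5

    def test_planted_landscape_minima(self, three_state_landscape):
        edges = np.arange(5.0, 20.01, 0.5)
        prof = pg.analytic_pmf(
            three_state_landscape, 0, 1.0, edges, n_quad=501
        )
        minima = pg.find_minima(prof, 4.0)
        found = sorted(p for p, _ in minima)
        assert len(found) == 3
        for target, pos in zip([8.6, 11.1, 15.3], found):
            assert abs(pos - target) <= 0.5  # within one bin width

    def test_classification_default_bands(self):
        bands = pg.default_state_bands()
        labelled = pg.classify_states(
            [(15.3, 0.0), (8.6, 1.0), (11.1, 0.5)], bands
        )
        assert [s for s, _, _ in labelled] == ["Active", "Inactive", "Intermediate"]

    def test_band_edge_goes_to_upper_band(self):
        bands = pg.default_state_bands()
        labelled = pg.classify_states([(10.0, 0.0), (13.0, 0.1)], bands)
        assert [s for s, _, _ in labelled] == ["Intermediate", "Active"]

    def test_unassigned_outside_bands(self):
        bands = pg.StateBands(bands=(("A", 0.0, 1.0),))
        assert pg.classify_states([(5.0, 0.0)], bands)[0][0] == "unassigned"

    def test_invalid_bands_rejected(self):
        with pytest.raises(InvalidParameterError):
            pg.StateBands(bands=(("A", 0.0, 1.0), ("B", 2.0, 3.0)))  # gap


class TestBindingTransitions:
    def test_hysteresis_counting(self):
        d = [0.5, 3.0, 0.5, 3.0, 0.5]
        assert pg.count_binding_transitions(d, 1.0, 2.0) == 4
        # chatter inside the hysteresis window is not counted
        d = [0.5, 1.5, 1.8, 1.5, 0.5]
        assert pg.count_binding_transitions(d, 1.0, 2.0) == 0

    def test_salt_bridge_flag(self):
        flags = pg.salt_bridge_formed([3.3, 5.0, 8.3])
        assert list(flags) == [True, False, False]
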