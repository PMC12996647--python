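"""Spatially constrained clustering, subunit summaries, and the
composite target score."""

import numpy as np
import pytest
from scipy import stats

from persotarget.hca_targeting import (
    HcaError,
    cluster_region,
    constrained_agglomerative_cluster,
    hca_target,
    score_subunits,
    spearman_distance_matrix,
    subunit_summary,
    voxel_adjacency,
)
from persotarget.volumetric_io import BinaryMask, BoldRun, VolumeGeometry


# ---------------------------------------------------------------------------
# Independent oracle: from-scratch greedy merge, recomputing every
# cluster-pair linkage as the mean of the *original* pairwise distances.


def greedy_merge_oracle(dist, adjacency, stop):
    n = dist.shape[0]
    clusters = {i: [i] for i in range(n)}

    def linkage(a, b):
        return np.mean([dist[i, j] for i in clusters[a] for j in clusters[b]])

    def adjacent(a, b):
        return any(adjacency[i, j] for i in clusters[a] for j in clusters[b])

    while len(clusters) > 1:
        best = None
        for a in sorted(clusters):
            for b in sorted(clusters):
                if a >= b or not adjacent(a, b):
                    continue
                d = linkage(a, b)
                key = (d, a, b)
                if best is None or key < best:
                    best = key
        if best is None or best[0] > stop:
            break
        _, a, b = best
        merged = sorted(clusters[a] + clusters[b])
        del clusters[a], clusters[b]
        clusters[min(merged)] = merged
    labels = np.empty(n, dtype=int)
    for lab, cid in enumerate(sorted(clusters)):
        labels[clusters[cid]] = lab
    return labels


def canonical(labels):
    """Relabel by first occurrence so labelings compare up to renaming."""
    seen = {}
    return tuple(seen.setdefault(l, len(seen)) for l in labels)


class TestSpearmanDistance:
    def test_identical_and_reversed_series(self):
        up = np.arange(20.0)
        ts = np.vstack([up, up, up[::-1]])
        d = spearman_distance_matrix(ts)
        assert d[0, 1] == pytest.approx(0.0, abs=1e-12)
        assert d[0, 2] == pytest.approx(2.0, abs=1e-12)

    def test_matches_rank_then_pearson_oracle(self):
        rng = np.random.default_rng(21)
        ts = rng.standard_normal((6, 20))
        d = spearman_distance_matrix(ts)
        for i in range(6):
            for j in range(6):
                ranks_i = stats.rankdata(ts[i])
                ranks_j = stats.rankdata(ts[j])
                rho = np.corrcoef(ranks_i, ranks_j)[0, 1]
                expected = 0.0 if i == j else 1 - rho
                assert d[i, j] == pytest.approx(expected, abs=1e-12)

    def test_constant_series_rejected(self):
        ts = np.vstack([np.ones(10), np.arange(10.0)])
        with pytest.raises(HcaError, match="constant"):
            spearman_distance_matrix(ts)


class TestAdjacency:
    @pytest.mark.parametrize(
        "connectivity,expected_neighbors", [(6, 6), (18, 18), (26, 26)]
    )
    def test_center_of_cube_neighbor_count(self, connectivity, expected_neighbors):
        voxels = np.array(list(np.ndindex(3, 3, 3)))
        adj = voxel_adjacency(voxels, connectivity)
        center = 13  # (1,1,1) in C order
        assert adj[center].sum() == expected_neighbors


class TestConstrainedClustering:
    def test_two_close_adjacent_voxels_merge(self):
        d = np.array([[0.0, 0.3], [0.3, 0.0]])
        adj = np.array([[False, True], [True, False]])
        labels = constrained_agglomerative_cluster(d, adj, stop=0.5)
        assert labels[0] == labels[1]

    def test_two_distant_voxels_stay_apart(self):
        d = np.array([[0.0, 0.7], [0.7, 0.0]])
        adj = np.array([[False, True], [True, False]])
        labels = constrained_agglomerative_cluster(d, adj, stop=0.5)
        assert labels[0] != labels[1]

    def test_non_adjacent_close_voxels_never_merge(self):
        d = np.array([[0.0, 0.01], [0.01, 0.0]])
        adj = np.zeros((2, 2), bool)
        labels = constrained_agglomerative_cluster(d, adj, stop=0.5)
        assert labels[0] != labels[1]

    def test_line_graph_matches_greedy_oracle(self):
        rng = np.random.default_rng(22)
        n = 10
        adj = np.zeros((n, n), bool)
        for i in range(n - 1):
            adj[i, i + 1] = adj[i + 1, i] = True
        for _ in range(25):
            d = rng.uniform(0.0, 1.0, size=(n, n))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            ours = constrained_agglomerative_cluster(d, adj, stop=0.5)
            oracle = greedy_merge_oracle(d, adj, stop=0.5)
            assert canonical(ours) == canonical(oracle)

    def test_disconnected_components_stay_separate(self):
        # two 2-voxel islands with tiny distances still give >= 2 clusters
        d = np.full((4, 4), 0.01)
        np.fill_diagonal(d, 0.0)
        adj = np.zeros((4, 4), bool)
        adj[0, 1] = adj[1, 0] = True
        adj[2, 3] = adj[3, 2] = True
        labels = constrained_agglomerative_cluster(d, adj, stop=0.5)
        assert labels[0] == labels[1]
        assert labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_labeling_invariant_to_voxel_enumeration_order(self):
        rng = np.random.default_rng(23)
        n = 9
        voxels = np.array(list(np.ndindex(3, 3, 1)))[:n]
        adj = voxel_adjacency(voxels, 26)
        d = rng.uniform(0, 1, (n, n))
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        base = constrained_agglomerative_cluster(d, adj, stop=0.6)
        perm = rng.permutation(n)
        inv = np.argsort(perm)
        permuted = constrained_agglomerative_cluster(d[np.ix_(perm, perm)],
                                                     adj[np.ix_(perm, perm)], stop=0.6)
        # mapping back through the permutation must give the same partition
        assert canonical(tuple(permuted[inv])) == canonical(tuple(base))


class TestSubunitSummary:
    def _geom(self):
        return VolumeGeometry(dims=(4, 4, 4), affine=np.diag([2.0, 2.0, 2.0, 1.0]))

    def test_singleton_subunit_is_its_own_summary(self):
        geom = self._geom()
        ts = np.array([[1.0, 2.0, 3.0, 2.0, 5.0]])
        voxels = np.array([[1, 1, 1]])
        subs = subunit_summary(ts, np.array([0]), voxels, geom)
        su = subs.subunits[0]
        np.testing.assert_array_equal(su.median_timecourse, ts[0])
        assert su.representative_voxel == (1, 1, 1)
        assert su.concentration == 0.0  # no voxel pairs

    def test_member_equal_to_median_is_representative(self):
        geom = self._geom()
        rng = np.random.default_rng(24)
        base = rng.standard_normal(30)
        ts = np.vstack([base + 0.5 * rng.standard_normal(30), base,
                        base - 0.5 * rng.standard_normal(30)])
        ts[1] = np.median(ts, axis=0)  # voxel B matches the median exactly
        voxels = np.array([[0, 0, 0], [0, 0, 1], [0, 0, 2]])
        subs = subunit_summary(ts, np.zeros(3, int), voxels, geom)
        assert subs.subunits[0].representative_voxel == (0, 0, 1)

    def test_concentration_two_voxels_4mm_apart(self):
        geom = self._geom()
        ts = np.array([[0.0, 1.0, 2.0], [0.1, 1.2, 1.9]])
        voxels = np.array([[0, 0, 0], [0, 0, 2]])  # 4 mm apart on 2 mm grid
        subs = subunit_summary(ts, np.zeros(2, int), voxels, geom)
        assert subs.subunits[0].concentration == pytest.approx(2 / 4)


class TestScoreSubunits:
    def _sets(self, dl_series, dl_sizes, dl_concs, sg_series, sg_sizes):
        from persotarget.hca_targeting import Subunit, SubunitSet

        def mk(series, sizes, concs):
            subs = []
            for s, n, c in zip(series, sizes, concs):
                subs.append(
                    Subunit(
                        voxel_indices=np.zeros((n, 3), int),
                        median_timecourse=s,
                        representative_voxel=(0, 0, 0),
                        representative_series=s,
                        size=n,
                        concentration=c,
                    )
                )
            return SubunitSet(subunits=subs, region_mask=None)

        return (
            mk(dl_series, dl_sizes, dl_concs),
            mk(sg_series, sg_sizes, [0.0] * len(sg_series)),
        )

    def test_weighted_sums_scale_with_sgacc_size(self):
        t = np.linspace(0, 4 * np.pi, 50)
        sg = np.sin(t)
        dl_a, dl_b = -np.sin(t), np.sin(t)  # r = -1 and +1
        dl, sgs = self._sets([dl_a, dl_b], [3, 3], [1.0, 1.0], [sg], [10])
        rows = score_subunits(dl, sgs)
        assert rows[0].weighted_corr_sum == pytest.approx(-10.0)
        assert rows[1].weighted_corr_sum == pytest.approx(10.0)
        # anticorrelation scores high: subunit A wins the weighted column
        assert rows[0].z_weighted > rows[1].z_weighted

    def test_z_columns_standardized_and_composite_is_sum(self):
        rng = np.random.default_rng(25)
        series = [rng.standard_normal(40) for _ in range(4)]
        sg = [rng.standard_normal(40)]
        dl, sgs = self._sets(series, [2, 5, 9, 3], [0.5, 1.5, 2.5, 1.0], sg, [7])
        rows = score_subunits(dl, sgs)
        for col in ("z_weighted", "z_conc", "z_size"):
            vals = np.array([getattr(r, col) for r in rows])
            assert abs(vals.mean()) < 1e-12
            assert vals.std(ddof=1) == pytest.approx(1.0, abs=1e-12)
        for r in rows:
            assert r.composite == pytest.approx(r.z_weighted + r.z_conc + r.z_size)

    def test_identical_parameter_triples_give_zero_z(self):
        t = np.linspace(0, 4 * np.pi, 50)
        s = np.sin(t)
        dl, sgs = self._sets([s, s], [3, 3], [1.0, 1.0], [np.cos(t)], [5])
        rows = score_subunits(dl, sgs)
        for r in rows:
            assert r.composite == pytest.approx(0.0, abs=1e-12)

    def test_spreadsheet_oracle_3x2(self):
        # hand-computed 3 DLPFC x 2 sgACC configuration
        t = np.linspace(0, 2 * np.pi, 16, endpoint=False)
        sg1, sg2 = np.sin(t), np.cos(t)
        dl_series = [np.sin(t), -np.sin(t), np.cos(t)]
        dl, sgs = self._sets(dl_series, [4, 6, 2], [2.0, 1.0, 3.0], [sg1, sg2], [10, 20])
        rows = score_subunits(dl, sgs)
        # r(sin,sin)=1, r(sin,cos)=0 -> weighted sums: 10, -10, 20
        w = np.array([10.0, -10.0, 20.0])
        zw = (-w - (-w).mean()) / (-w).std(ddof=1)
        conc = np.array([2.0, 1.0, 3.0])
        zc = (conc - conc.mean()) / conc.std(ddof=1)
        size = np.array([4.0, 6.0, 2.0])
        zs = (size - size.mean()) / size.std(ddof=1)
        for r, ew, ec, es in zip(rows, zw, zc, zs):
            assert r.z_weighted == pytest.approx(ew)
            assert r.z_conc == pytest.approx(ec)
            assert r.z_size == pytest.approx(es)
            assert r.composite == pytest.approx(ew + ec + es)

    def test_single_dlpfc_subunit_rejected(self):
        t = np.linspace(0, 4 * np.pi, 50)
        dl, sgs = self._sets([np.sin(t)], [3], [1.0], [np.cos(t)], [5])
        with pytest.raises(HcaError, match="2 DLPFC subunits"):
            score_subunits(dl, sgs)


class TestHcaTarget:
    def test_planted_blob_wins_and_target_is_deterministic(self, recovery_cohort):
        masks = recovery_cohort["masks"]
        run = recovery_cohort["cleaned"]["sub-00"][0]
        t1 = hca_target(run, masks.dlpfc, masks.sgacc)
        t2 = hca_target(run, masks.dlpfc, masks.sgacc)
        assert t1.world_mm == t2.world_mm
        blob = set(map(tuple, masks.target_blob.voxel_indices()))
        from persotarget.volumetric_io import world_to_voxel

        assert world_to_voxel(t1.world_mm, run.geometry) in blob

    def test_target_inside_search_mask(self, recovery_cohort):
        masks = recovery_cohort["masks"]
        run = recovery_cohort["cleaned"]["sub-01"][1]
        t = hca_target(run, masks.dlpfc, masks.sgacc)
        from persotarget.volumetric_io import world_to_voxel

        assert masks.dlpfc.data[world_to_voxel(t.world_mm, run.geometry)]
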