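"""Adjacency, SNR difference maps, cluster forming, and the permutation test."""

import numpy as np
import pytest

from stimrel.containers import ChannelGeometry
from stimrel.clusters import (
    adjacency_from_coords,
    bh_reject,
    cluster_permutation_test,
    form_clusters,
    snr_difference_map,
)
from stimrel.surrogates import NullDistribution, ReliabilityMap


def grid_geometry(shape, spacing=8.0):
    idx = np.indices(shape).reshape(3, -1).T * spacing
    n = len(idx)
    return ChannelGeometry(
        coords=idx.astype(float), labels=[f"c{i}" for i in range(n)],
        region_tags=["x"] * n, kind="grid", spacing_mm=spacing,
    )


def chain_geometry(n, spacing=8.0):
    coords = np.column_stack([np.arange(n) * spacing, np.zeros(n), np.zeros(n)])
    return ChannelGeometry(
        coords=coords, labels=[f"c{i}" for i in range(n)],
        region_tags=["x"] * n, kind="grid", spacing_mm=spacing,
    )


def rel_map(z, band="theta"):
    z = np.asarray(z, dtype=float)
    return ReliabilityMap(
        ga_z=np.tanh(z) * 0.1, z=z, p=np.full_like(z, 0.5),
        fdr_pass=np.zeros(len(z), dtype=bool),
        channel_mask=np.ones(len(z), dtype=bool),
        q=0.05, sided="one_sided_positive", meta={"band": band},
    )


class TestAdjacency:
    def test_default_threshold_gives_18_connectivity_on_8mm_grid(self):
        geom = grid_geometry((3, 3, 3))
        graph = adjacency_from_coords(geom)
        assert graph.max_dist_mm == pytest.approx(12.0)
        # brute-force oracle: edge iff distance <= 12 mm
        d = np.linalg.norm(geom.coords[:, None] - geom.coords[None, :], axis=-1)
        oracle = (d <= 12.0) & (d > 0)
        for i in range(geom.n_channels):
            assert set(graph.neighbors[i]) == set(np.nonzero(oracle[i])[0])
        center = 13  # middle of the 3x3x3 cube
        assert len(graph.neighbors[center]) == 18  # 6 face + 12 edge-diagonal

    def test_distant_channels_unconnected(self):
        geom = chain_geometry(2, spacing=100.0)
        graph = adjacency_from_coords(geom, max_dist_mm=12.0)
        assert graph.edges.shape[0] == 0

    def test_symmetry_and_no_self_edges(self, rng):
        coords = rng.uniform(0, 40, (30, 3))
        geom = ChannelGeometry(coords, [f"c{i}" for i in range(30)], ["x"] * 30, kind="montage")
        graph = adjacency_from_coords(geom, max_dist_mm=15.0)
        for i in range(30):
            assert i not in graph.neighbors[i]
            for j in graph.neighbors[i]:
                assert i in graph.neighbors[j]

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            adjacency_from_coords(chain_geometry(3), max_dist_mm=0.0)


class TestSnrDifferenceMap:
    def test_equal_maps_give_zero(self, rng):
        z = rng.standard_normal(10)
        dz, mask = snr_difference_map(rel_map(z), rel_map(z.copy()), abs_b=False)
        assert np.allclose(dz, 0.0)
        assert mask.all()

    def test_abs_b_uses_magnitude(self):
        dz, _ = snr_difference_map(rel_map([1.0, 1.0]), rel_map([-3.0, 3.0]), abs_b=True)
        assert np.allclose(dz, [2.0, 2.0])
        dz2, _ = snr_difference_map(rel_map([1.0, 1.0]), rel_map([-3.0, 3.0]), abs_b=False)
        assert np.allclose(dz2, [-4.0, 2.0])

    def test_band_mismatch_rejected(self):
        with pytest.raises(ValueError, match="band mismatch"):
            snr_difference_map(rel_map([0.0], band="theta"), rel_map([0.0], band="alpha"))

    def test_masked_channels_propagate(self, rng):
        a = rel_map(rng.standard_normal(4))
        b = rel_map(rng.standard_normal(4))
        a.channel_mask[2] = False
        dz, mask = snr_difference_map(a, b)
        assert not mask[2] and np.isnan(dz[2])


class TestFormClusters:
    def test_constant_map_has_no_clusters(self):
        graph = adjacency_from_coords(chain_geometry(10))
        res = form_clusters(np.full(10, 1.5), graph)
        assert res.clusters == []
        assert res.threshold_hi == pytest.approx(1.5)

    def test_hand_enumerated_chain_components(self):
        values = np.array([0.0, 5.0, 6.0, 0.0, 7.0] + [0.0] * 92)
        graph = adjacency_from_coords(chain_geometry(len(values)))
        res = form_clusters(values, graph)
        # hi threshold is a percentile of the map's own values, between 0 and 5
        assert 0.0 < res.threshold_hi < 5.0
        pos = sorted([(c.size, c.total) for c in res.clusters if c.tail == "positive"])
        assert pos == [(1, 7.0), (2, 11.0)]
        assert res.max_cluster("positive").total == pytest.approx(11.0)

    def test_sums_equal_member_totals_and_membership_unique(self, rng):
        graph = adjacency_from_coords(grid_geometry((4, 4, 2)))
        dz = rng.standard_normal(32)
        res = form_clusters(dz, graph)
        seen = set()
        for c in res.clusters:
            assert c.total == pytest.approx(dz[c.channels].sum())
            assert seen.isdisjoint(c.channels.tolist())
            seen.update(c.channels.tolist())

    def test_components_match_scipy_oracle(self, rng):
        from scipy.sparse import coo_matrix
        from scipy.sparse.csgraph import connected_components

        geom = ChannelGeometry(
            rng.uniform(0, 60, (60, 3)), [f"c{i}" for i in range(60)], ["x"] * 60, kind="montage"
        )
        graph = adjacency_from_coords(geom, max_dist_mm=20.0)
        dz = rng.standard_normal(60)
        res = form_clusters(dz, graph)
        supra = dz > res.threshold_hi
        idx = np.nonzero(supra)[0]
        sub = {v: k for k, v in enumerate(idx)}
        rows, cols = [], []
        for i, j in graph.edges:
            if supra[i] and supra[j]:
                rows += [sub[i], sub[j]]
                cols += [sub[j], sub[i]]
        n_sub = len(idx)
        adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n_sub, n_sub))
        n_comp, labels = connected_components(adj, directed=False)
        ours = sorted(
            tuple(sorted(c.channels)) for c in res.clusters if c.tail == "positive"
        )
        oracle = sorted(
            tuple(sorted(idx[labels == k])) for k in range(n_comp)
        )
        assert ours == oracle

    def test_label_permutation_invariance(self, rng):
        geom = grid_geometry((3, 3, 2))
        graph = adjacency_from_coords(geom)
        dz = rng.standard_normal(18)
        res = form_clusters(dz, graph)
        perm = rng.permutation(18)
        inv = np.argsort(perm)
        geom_p = ChannelGeometry(
            geom.coords[perm], [f"c{i}" for i in range(18)], ["x"] * 18, kind="grid", spacing_mm=8.0
        )
        res_p = form_clusters(dz[perm], adjacency_from_coords(geom_p))
        sums = sorted(round(c.total, 9) for c in res.clusters)
        sums_p = sorted(round(c.total, 9) for c in res_p.clusters)
        assert sums == sums_p


class TestClusterPermutationTest:
    def _nulls(self, rng, C, n=500):
        a = NullDistribution(draws=rng.normal(0, 0.01, (n, C)), channel_mask=np.ones(C, dtype=bool))
        b = NullDistribution(draws=rng.normal(0, 0.01, (n, C)), channel_mask=np.ones(C, dtype=bool))
        return a, b

    def test_dominant_cluster_attains_minimum_p(self, rng):
        geom = grid_geometry((4, 4, 2))
        graph = adjacency_from_coords(geom)
        nullA, nullB = self._nulls(rng, 32)
        dz = rng.normal(0, 1, 32)
        dz[:6] += 50.0
        emp = form_clusters(dz, graph)
        res = cluster_permutation_test(nullA, nullB, emp, graph, n_maps=200, seed=0)
        assert res.p_values["positive"] == pytest.approx(1 / 201)

    def test_injected_block_lowers_p(self, rng):
        geom = grid_geometry((4, 4, 4))
        graph = adjacency_from_coords(geom)
        nullA, nullB = self._nulls(rng, 64)
        base = rng.normal(0, 1, 64)
        emp0 = form_clusters(base, graph)
        r0 = cluster_permutation_test(nullA, nullB, emp0, graph, n_maps=300, seed=1)
        boosted = base.copy()
        boosted[:8] += 10.0
        emp1 = form_clusters(boosted, graph)
        r1 = cluster_permutation_test(nullA, nullB, emp1, graph, n_maps=300, seed=1)
        assert r1.p_values["positive"] < r0.p_values.get("positive", 1.0)

    def test_missing_channels_excluded(self, rng):
        geom = grid_geometry((4, 4, 2))
        graph = adjacency_from_coords(geom)
        nullA, nullB = self._nulls(rng, 32)
        dz = rng.normal(0, 1, 32)
        mask = np.ones(32, dtype=bool)
        mask[:5] = False
        emp = form_clusters(dz, graph, mask=mask)
        assert all(np.all(mask[c.channels]) for c in emp.clusters)
        res = cluster_permutation_test(nullA, nullB, emp, graph, n_maps=100, seed=2)
        assert set(res.p_values) <= {"positive", "negative"}


class TestBhReject:
    def test_matches_brute_force_on_random_pvalues(self, rng):
        for _ in range(20):
            p = rng.uniform(0, 1, rng.integers(1, 12))
            q = 0.05
            m = len(p)
            order = np.argsort(p)
            passed = np.nonzero(np.sort(p) <= (np.arange(1, m + 1) / m) * q)[0]
            k = passed.max() + 1 if len(passed) else 0
            brute = np.zeros(m, dtype=bool)
            brute[order[:k]] = True
            assert np.array_equal(bh_reject(p, q), brute)
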