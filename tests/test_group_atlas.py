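"""Spherical k-means, silhouette, label matching, model-order selection."""

import itertools

import numpy as np
import pytest
from sklearn.metrics import silhouette_score

from fcparc import (
    Parcellation,
    ValidationError,
    average_profiles,
    dice,
    kmeans_cosine,
    match_labels,
    reassign_small_clusters,
    select_model_order,
    silhouette_cosine,
)
from fcparc.connectivity import ConnectivityProfileMatrix


def _pm(values):
    # bare profile container for constructed geometry (bypasses the [-1, 1]
    # correlation check so arbitrary point clouds can be clustered)
    values = np.asarray(values, dtype=float)
    m = ConnectivityProfileMatrix.__new__(ConnectivityProfileMatrix)
    m.values = values
    m.roi_indices = np.arange(values.shape[0])
    m.self_policy = "masked-to-zero"
    m.excluded = np.array([], dtype=np.int64)
    return m


class TestAverageProfiles:
    def test_mean_identity_and_arithmetic(self):
        a = _pm(np.full((3, 4), 0.2))
        b = _pm(np.full((3, 4), 0.6))
        assert np.allclose(average_profiles([a, a]).values, a.values)
        assert np.allclose(average_profiles([a, b]).values, 0.4)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        mats = [_pm(rng.uniform(-1, 1, (4, 6))) for _ in range(5)]
        m1 = average_profiles(mats).values
        m2 = average_profiles(mats[::-1]).values
        assert np.allclose(m1, m2, atol=1e-12)

    def test_shape_mismatch(self):
        with pytest.raises(ValidationError):
            average_profiles([_pm(np.zeros((3, 4))), _pm(np.zeros((3, 5)))])


def spherical_objective(xn, labels, k):
    obj = 0.0
    for c in range(k):
        members = xn[labels == c]
        if len(members) == 0:
            return np.inf
        centroid = members.mean(axis=0)
        n = np.linalg.norm(centroid)
        if n == 0:
            continue
        obj += np.sum(1.0 - members @ (centroid / n))
    return obj


class TestKmeansCosine:
    def test_orthogonal_pairs_recovered_exactly(self):
        base = np.eye(3)
        x = np.repeat(base, 2, axis=0) * np.array([[1], [2], [1], [3], [2], [1]])
        atlas = kmeans_cosine(_pm(x), 3, n_restarts=20, seed=0)
        labels = atlas.parcellation.labels
        assert labels[0] == labels[1] and labels[2] == labels[3] and labels[4] == labels[5]
        assert len({labels[0], labels[2], labels[4]}) == 3
        assert atlas.aggregate_distance == pytest.approx(0.0, abs=1e-12)

    def test_matches_exhaustive_partition_oracle(self):
        rng = np.random.default_rng(1)
        x = np.vstack([
            rng.normal([5, 0, 0], 0.3, (4, 3)),
            rng.normal([0, 5, 0], 0.3, (4, 3)),
        ])
        xn = x / np.linalg.norm(x, axis=1, keepdims=True)
        best_obj, best_assign = np.inf, None
        for bits in itertools.product([0, 1], repeat=8):
            labels = np.array(bits)
            if labels.min() == labels.max():
                continue
            obj = spherical_objective(xn, labels, 2)
            if obj < best_obj:
                best_obj, best_assign = obj, labels
        atlas = kmeans_cosine(_pm(x), 2, n_restarts=20, seed=0)
        got = atlas.parcellation.labels - 1
        assert np.array_equal(got, best_assign) or np.array_equal(1 - got, best_assign)
        assert atlas.aggregate_distance == pytest.approx(best_obj, abs=1e-9)

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((20, 5))
        a = kmeans_cosine(_pm(x), 3, n_restarts=10, seed=4)
        b = kmeans_cosine(_pm(x), 3, n_restarts=10, seed=4)
        assert np.array_equal(a.parcellation.labels, b.parcellation.labels)
        assert a.aggregate_distance == b.aggregate_distance

    def test_lloyd_objective_monotone(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((40, 6))
        kmeans_cosine(_pm(x), 4, n_restarts=10, seed=0, check_monotone=True)

    def test_centroids_unit_norm(self):
        rng = np.random.default_rng(5)
        atlas = kmeans_cosine(_pm(rng.standard_normal((15, 4))), 3, 5, seed=1)
        assert np.allclose(np.linalg.norm(atlas.centroids, axis=1), 1.0, atol=1e-10)


class TestSilhouette:
    def test_two_tight_orthogonal_clusters(self):
        rng = np.random.default_rng(0)
        x = np.vstack([rng.normal([10, 0], 0.01, (5, 2)),
                       rng.normal([0, 10], 0.01, (5, 2))])
        labels = np.array([1] * 5 + [2] * 5)
        assert silhouette_cosine(_pm(x), labels) > 0.9

    def test_identical_points_tie_rule(self):
        x = np.ones((6, 3))
        labels = np.array([1, 1, 1, 2, 2, 2])
        assert silhouette_cosine(_pm(x), labels) == 0.0

    def test_matches_double_loop_oracle_and_sklearn(self):
        rng = np.random.default_rng(7)
        for trial in range(20):
            x = rng.standard_normal((7, 4)) + 2.0
            labels = np.array([1, 1, 2, 2, 2, 3, 3])
            xn = x / np.linalg.norm(x, axis=1, keepdims=True)
            d = 1 - xn @ xn.T
            s_vals = []
            for i in range(7):
                own = [j for j in range(7) if labels[j] == labels[i] and j != i]
                a = np.mean([d[i, j] for j in own])
                b = min(np.mean([d[i, j] for j in range(7) if labels[j] == c])
                        for c in {1, 2, 3} if c != labels[i])
                s_vals.append((b - a) / max(a, b))
            assert silhouette_cosine(_pm(x), labels) == pytest.approx(
                np.mean(s_vals), abs=1e-12)
            skl = silhouette_score(x, labels, metric="cosine")
            assert silhouette_cosine(_pm(x), labels) == pytest.approx(skl, abs=1e-8)

    def test_single_cluster_undefined(self):
        with pytest.raises(ValidationError):
            silhouette_cosine(_pm(np.ones((4, 2))), np.array([1, 1, 1, 1]))


class TestMatchLabels:
    def test_permutation_recovery(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(1, 4, 30)
        a = Parcellation(labels, 3)
        perm = {1: 3, 2: 1, 3: 2}
        b = Parcellation(np.array([perm[l] for l in labels]), 3)
        matched, mapping = match_labels(a, b)
        assert np.array_equal(matched.labels, a.labels)
        assert dice(a, matched).weighted_mean == 1.0

    def test_identity(self):
        a = Parcellation(np.array([1, 2, 3, 1]), 3)
        matched, mapping = match_labels(a, a)
        assert mapping == {1: 1, 2: 2, 3: 3}

    def test_matches_exhaustive_permutation_search(self):
        rng = np.random.default_rng(2)
        for trial in range(30):
            la = rng.integers(1, 4, 10)
            lb = rng.integers(1, 4, 10)
            if len(np.unique(la)) < 3 or len(np.unique(lb)) < 3:
                continue
            a, b = Parcellation(la, 3), Parcellation(lb, 3)
            best = max(
                (sum(np.sum((lb == old) & (la == new))
                     for old, new in zip((1, 2, 3), perm)), perm)
                for perm in itertools.permutations((1, 2, 3))
            )[0]
            matched, mapping = match_labels(a, b)
            got = sum(np.sum((matched.labels == l) & (la == l)) for l in (1, 2, 3))
            assert got == best


class TestSelectModelOrder:
    def test_interior_local_maxima(self):
        ks = [2, 3, 4, 5, 6]
        prods = [0.5, 0.7, 0.6, 0.8, 0.4]
        assert select_model_order(ks, prods, np.ones(5)) == [3, 5]

    def test_monotone_increasing_selects_nothing(self):
        assert select_model_order([2, 3, 4], [0.1, 0.2, 0.3], np.ones(3)) == []

    def test_plateau_prefers_smaller_k(self):
        assert select_model_order([2, 3, 4, 5], [0.5, 0.7, 0.7, 0.4], np.ones(4)) == [3]

    def test_too_few_orders(self):
        with pytest.raises(ValidationError):
            select_model_order([2, 3], [0.1, 0.2], [1, 1])


class TestReassignSmallClusters:
    def make_parc_mesh(self, mesh2, template4):
        return template4, mesh2

    def test_singleton_absorbed_by_majority(self, mesh2, template4):
        labels = template4.labels.copy()
        roi = mesh2.roi_indices
        pos = {int(v): i for i, v in enumerate(roi)}
        # pick an interior vertex of network 1 and flip it to network 2
        for i, v in enumerate(roi):
            nb = [pos[int(w)] for w in mesh2.neighbors[v] if int(w) in pos]
            if labels[i] == 1 and len(nb) >= 5 and all(labels[j] == 1 for j in nb):
                labels[i] = 2
                target = i
                break
        parc = Parcellation(labels, 4)
        rng = np.random.default_rng(0)
        profiles = _pm(rng.standard_normal((len(roi), 30)))
        area = float(mesh2.vertex_area[roi[target]])
        out = reassign_small_clusters(parc, mesh2, profiles, min_area_mm2=area + 1)
        assert out.labels[target] == 1

    def test_tie_broken_by_profile_correlation(self):
        # wheel mesh: center vertex 0, inner hexagon 1..6, outer hexagon 7..12.
        # Center is a singleton network with 3 neighbors of network 1 and 3 of
        # network 2 (exact frequency tie); its profile matches network 1.
        from fcparc import SurfaceMesh

        ang_in = np.arange(6) * np.pi / 3
        ang_out = ang_in + np.pi / 6
        coords = np.vstack([
            [0.0, 0.0, 0.0],
            np.c_[np.cos(ang_in), np.sin(ang_in), np.zeros(6)],
            2.0 * np.c_[np.cos(ang_out), np.sin(ang_out), np.zeros(6)],
        ])
        tris = []
        for i in range(6):
            a, b = 1 + i, 1 + (i + 1) % 6
            c, d = 7 + i, 7 + (i + 1) % 6
            tris += [(0, a, b), (a, b, c), (b, d, c)]
        mesh = SurfaceMesh.from_arrays(coords, np.array(tris))
        labels = np.array([3] + [1, 1, 1, 2, 2, 2] + [1, 1, 1, 2, 2, 2])
        parc = Parcellation(labels, 3)
        rng = np.random.default_rng(1)
        sig_a, sig_b = rng.standard_normal(20), rng.standard_normal(20)
        values = np.empty((13, 20))
        values[labels == 1] = sig_a
        values[labels == 2] = sig_b
        values[0] = 0.9 * sig_a + 0.1 * rng.standard_normal(20)
        threshold = float(mesh.vertex_area[0]) + 1e-9  # only the center is small
        assert all(mesh.vertex_area[labels == 1].sum() > threshold
                   for lab in (1, 2))
        out = reassign_small_clusters(parc, mesh, _pm(values),
                                      min_area_mm2=threshold)
        assert out.labels[0] == 1  # the network whose mean profile matches best

    def test_threshold_is_inclusive(self, mesh2, template4):
        # "10 mm^2 or smaller": a component of exactly the threshold area moves
        labels = template4.labels.copy()
        roi = mesh2.roi_indices
        pos = {int(v): i for i, v in enumerate(roi)}
        for i, v in enumerate(roi):
            nb = [pos[int(w)] for w in mesh2.neighbors[v] if int(w) in pos]
            if labels[i] == 1 and len(nb) >= 5 and all(labels[j] == 1 for j in nb):
                labels[i] = 2
                target = i
                break
        parc = Parcellation(labels, 4)
        profiles = _pm(np.random.default_rng(0).standard_normal((len(roi), 10)))
        area = float(mesh2.vertex_area[roi[target]])
        out = reassign_small_clusters(parc, mesh2, profiles, min_area_mm2=area)
        assert out.labels[target] == 1

    def test_never_creates_label_or_empties_largest(self, mesh2, template4):
        rng = np.random.default_rng(3)
        roi = mesh2.roi_indices
        profiles = _pm(rng.standard_normal((len(roi), 15)))
        out = reassign_small_clusters(template4, mesh2, profiles, min_area_mm2=10.0)
        assert set(np.unique(out.labels)) <= set(range(1, 5))
        largest = np.argmax(template4.network_sizes()) + 1
        assert np.sum(out.labels == largest) > 0
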