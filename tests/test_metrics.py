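"""Dice, homogeneity, specificity, and variability metrics."""

import numpy as np
import pytest

from fcparc import (
    Parcellation,
    TaskZMap,
    TimeSeriesMatrix,
    ValidationError,
    connectional_homogeneity,
    dice,
    functional_inhomogeneity,
    percent_effect,
    variability_summary,
)


class TestDice:
    def test_identity(self):
        p = Parcellation(np.array([1, 2, 2, 1, 3]), 3)
        rep = dice(p, p)
        assert all(v == 1.0 for v in rep.per_network.values())
        assert rep.weighted_mean == 1.0

    def test_printed_formula(self):
        a = Parcellation(np.r_[np.ones(10, int), np.full(10, 2)], 2)
        b_labels = a.labels.copy()
        b_labels[:5] = 2
        b_labels[10:15] = 1
        b = Parcellation(b_labels, 2)
        rep = dice(a, b)
        assert rep.per_network[1] == pytest.approx(2 * 5 / (10 + 10))

    def test_matches_brute_force_counting(self, rng):
        for _ in range(100):
            la = rng.integers(1, 4, 12)
            lb = rng.integers(1, 4, 12)
            rep = dice(Parcellation(la, 3), Parcellation(lb, 3))
            vals = []
            for lab in (1, 2, 3):
                v1 = sum(1 for x in la if x == lab)
                v2 = sum(1 for x in lb if x == lab)
                ov = sum(1 for x, y in zip(la, lb) if x == lab and y == lab)
                if v1 + v2:
                    vals.append(2 * ov / (v1 + v2))
                    assert rep.per_network[lab] == 2 * ov / (v1 + v2)
            assert rep.weighted_mean == pytest.approx(np.mean(vals), abs=1e-15)

    def test_symmetry(self, rng):
        la, lb = rng.integers(1, 4, 20), rng.integers(1, 4, 20)
        a, b = Parcellation(la, 3), Parcellation(lb, 3)
        assert dice(a, b).weighted_mean == dice(b, a).weighted_mean


class TestFunctionalInhomogeneity:
    def test_constant_within_networks_is_zero(self):
        parc = Parcellation(np.array([1, 1, 2, 2]), 2)
        zm = TaskZMap(np.array([3.0, 3.0, -1.0, -1.0]))
        assert functional_inhomogeneity(zm, parc).weighted_mean == 0.0

    def test_weighted_arithmetic_with_sample_sd(self):
        parc = Parcellation(np.array([1, 1, 2, 2]), 2)
        zm = TaskZMap(np.array([1.0, 1.0, 0.0, 2.0]))
        # sd_1 = 0 (n=2), sd_2 = sqrt(2) with ddof=1; weighted: (0*2 + 1.41421*2)/4
        rep = functional_inhomogeneity(zm, parc)
        assert rep.weighted_mean == pytest.approx(np.sqrt(2) / 2, abs=1e-5)
        assert rep.weighted_mean == pytest.approx(0.70711, abs=1e-5)

    def test_merging_differently_activated_networks_increases(self, rng):
        # between-network activation differences dominate: pooling two
        # differently activated networks inflates the within-network sd
        means = np.array([0.0, 3.0, 6.0])
        for _ in range(50):
            labels = np.r_[np.ones(4, int), np.full(4, 2), np.full(4, 3)]
            z = means[labels - 1] + 0.1 * rng.standard_normal(12)
            parc = Parcellation(labels, 3)
            merged = Parcellation(np.where(labels == 3, 2, labels), 2)
            zm = TaskZMap(z)
            assert (functional_inhomogeneity(zm, merged).weighted_mean
                    > functional_inhomogeneity(zm, parc).weighted_mean)

    def test_singleton_network_warns(self):
        parc = Parcellation(np.array([1, 1, 2]), 2)
        with pytest.warns(UserWarning, match="single vertex"):
            rep = functional_inhomogeneity(TaskZMap(np.array([0.0, 1.0, 5.0])), parc)
        assert rep.per_network[2] == 0.0


def make_ts_with_pair_correlation(r, n_t=4000, seed=0):
    rng = np.random.default_rng(seed)
    shared = rng.standard_normal(n_t)
    # mixing weights giving exact population correlation r
    a = np.sqrt(abs(r))
    x = a * shared + np.sqrt(1 - a**2) * rng.standard_normal(n_t)
    y = np.sign(r) * a * shared + np.sqrt(1 - a**2) * rng.standard_normal(n_t)
    return x, y


class TestConnectionalHomogeneity:
    def test_two_vertex_network_equals_atanh_r(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(100)
        y = rng.standard_normal(100)
        parc = Parcellation(np.array([1, 1, 2, 2]), 2)
        data = np.vstack([x, x + y, y, -y])
        ts = TimeSeriesMatrix(data, 2.8)
        rep = connectional_homogeneity(ts, parc)
        r12 = np.corrcoef(x, x + y)[0, 1]
        assert rep.per_network[1] == pytest.approx(np.arctanh(r12), abs=1e-10)
        # network 2 holds an exactly anti-correlated pair: clipped atanh(-1)
        assert rep.per_network[2] == pytest.approx(-np.arctanh(1 - 1e-7), abs=1e-6)

    def test_weighted_mean_arithmetic(self):
        # network 1: pair with r=0.5 -> atanh(0.5); network 2: r=0 -> 0
        t = np.arange(400)
        e1 = np.cos(2 * np.pi * 3 * t / 400)
        e2 = np.sin(2 * np.pi * 3 * t / 400)
        e3 = np.cos(2 * np.pi * 7 * t / 400)
        v1 = e1
        v2 = 0.5 * e1 + np.sqrt(0.75) * e2  # corr(v1, v2) = 0.5 exactly
        parc = Parcellation(np.array([1, 1, 2, 2]), 2)
        ts = TimeSeriesMatrix(np.vstack([v1, v2, e3, e2]), 2.8)
        rep = connectional_homogeneity(ts, parc)
        assert rep.per_network[1] == pytest.approx(0.549306, abs=1e-5)
        assert abs(rep.per_network[2]) < 1e-10
        assert rep.weighted_mean == pytest.approx(0.549306 / 2, abs=1e-5)

    def test_matches_double_loop_oracle(self, rng):
        data = rng.standard_normal((5, 60))
        parc = Parcellation(np.array([1, 1, 1, 2, 2]), 2)
        rep = connectional_homogeneity(TimeSeriesMatrix(data, 2.8), parc)
        for lab, members in ((1, [0, 1, 2]), (2, [3, 4])):
            zs = []
            for i_idx, i in enumerate(members):
                for j in members[i_idx + 1:]:
                    r = np.corrcoef(data[i], data[j])[0, 1]
                    zs.append(np.arctanh(np.clip(r, -1 + 1e-7, 1 - 1e-7)))
            assert rep.per_network[lab] == pytest.approx(np.mean(zs), abs=1e-10)

    def test_generating_parcellation_maximizes_homogeneity(self):
        t = np.arange(200)
        e1 = np.cos(2 * np.pi * 3 * t / 200)
        e2 = np.sin(2 * np.pi * 5 * t / 200)
        data = np.vstack([e1, e1, e2, e2])
        ts = TimeSeriesMatrix(data, 2.8)
        true_parc = Parcellation(np.array([1, 1, 2, 2]), 2)
        best = connectional_homogeneity(ts, true_parc).weighted_mean
        for labels in ([1, 2, 1, 2], [1, 2, 2, 1]):
            alt = connectional_homogeneity(ts, Parcellation(np.array(labels), 2))
            assert alt.weighted_mean < best


class TestPercentEffect:
    def test_arithmetic(self):
        parc = Parcellation(np.array([1, 1, 2, 3, 4]), 4)
        effect = np.array([2.0, 1.0, 1.0, 0.0, 0.0])
        rep = percent_effect(effect, parc)
        assert rep.per_network == {1: 75.0, 2: 25.0, 3: 0.0, 4: 0.0}

    def test_single_network_holds_all(self):
        parc = Parcellation(np.array([1, 1, 2]), 2)
        rep = percent_effect(np.array([3.0, 4.0, 0.0]), parc)
        assert rep.per_network[1] == 100.0

    def test_conservation(self, rng):
        for _ in range(20):
            labels = rng.integers(1, 4, 15)
            effect = rng.standard_normal(15)
            if abs(effect.sum()) < 1e-6:
                continue
            rep = percent_effect(effect, Parcellation(labels, 3))
            assert sum(rep.per_network.values()) == pytest.approx(100.0, abs=1e-9)

    def test_zero_total_rejected(self):
        parc = Parcellation(np.array([1, 2]), 2)
        with pytest.raises(ValidationError):
            percent_effect(np.array([1.0, -1.0]), parc)


class TestVariabilitySummary:
    def test_identical_parcellations_give_unity(self):
        p = Parcellation(np.array([1, 1, 2, 2]), 2)
        parcs = {(s, ses): p for s in ("a", "b") for ses in ("1", "2")}
        summary = variability_summary(parcs)
        assert summary.intra == {"a": 1.0, "b": 1.0}
        assert summary.inter == {"a": 1.0, "b": 1.0}

    def test_hand_computed_toy(self):
        pa1 = Parcellation(np.array([1, 1, 2, 2]), 2)
        pa2 = Parcellation(np.array([1, 1, 2, 2]), 2)
        pb1 = Parcellation(np.array([1, 2, 2, 2]), 2)
        pb2 = Parcellation(np.array([1, 1, 1, 2]), 2)
        parcs = {("a", "1"): pa1, ("a", "2"): pa2, ("b", "1"): pb1, ("b", "2"): pb2}
        summary = variability_summary(parcs)
        assert summary.intra["a"] == 1.0
        # b session1 vs session2: net1 dice 2*1/(1+3)=0.5; net2 2*1/(3+1)=0.5
        assert summary.intra["b"] == pytest.approx(0.5)
        # a vs b: four cross pairs, each hand-computable
        d_a1_b1 = np.mean([2 * 1 / (2 + 1), 2 * 2 / (2 + 3)])
        d_a1_b2 = np.mean([2 * 2 / (2 + 3), 2 * 1 / (2 + 1)])
        expected = np.mean([d_a1_b1, d_a1_b2, d_a1_b1, d_a1_b2])
        assert summary.inter["a"] == pytest.approx(expected)
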