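import itertools
import math

import numpy as np
import pandas as pd
import pytest

from microeuk.diversity import (
    alpha_diversity,
    bray_curtis,
    chla_level,
    correlate,
    group_compare,
    nmds,
    permanova,
    quadratic_fit,
    sorensen_similarity,
)
from microeuk.io import CommunityTable, DistanceMatrix


def ct(rows, samples=None):
    samples = samples or [f"s{i}" for i in range(len(rows))]
    return CommunityTable(
        pd.DataFrame(rows, index=samples, columns=[f"a{j}" for j in range(len(rows[0]))])
    )


class TestAlpha:
    def test_uniform_equals_log_richness(self):
        a = alpha_diversity(ct([[10, 10, 10, 10]]))
        assert a["shannon"].iloc[0] == pytest.approx(math.log(4))
        assert a["richness"].iloc[0] == 4

    def test_single_asv(self):
        a = alpha_diversity(ct([[0, 9, 0]]))
        assert a["shannon"].iloc[0] == 0
        assert a["richness"].iloc[0] == 1

    def test_base2_hand_value(self):
        a = alpha_diversity(ct([[50, 30, 20]]), shannon_base=2)
        assert a["shannon"].iloc[0] == pytest.approx(1.4855, abs=1e-4)

    def test_shannon_bounded_by_log_richness(self, rng):
        table = ct(rng.integers(0, 30, size=(8, 25)).tolist())
        a = alpha_diversity(table)
        ok = a["richness"] >= 1
        assert (a.loc[ok, "shannon"] <= np.log(a.loc[ok, "richness"]) + 1e-9).all()


class TestResemblance:
    def test_bray_curtis_hand_value(self):
        d = bray_curtis(ct([[1, 2, 0], [0, 2, 4]]))
        assert d.values[0, 1] == pytest.approx(5 / 9)

    def test_bray_curtis_extremes(self):
        d = bray_curtis(ct([[1, 2, 3], [1, 2, 3], [0, 0, 7]]))
        assert d.values[0, 1] == 0
        assert d.values[0, 2] == pytest.approx(7 / 13)
        disjoint = bray_curtis(ct([[5, 0], [0, 5]]))
        assert disjoint.values[0, 1] == 1

    def test_sorensen_hand_value(self):
        # {a,b,c} vs {b,c,d}: 2*2/(3+3)
        s = sorensen_similarity(ct([[1, 1, 1, 0], [0, 1, 1, 1]]))
        assert s.values[0, 1] == pytest.approx(2 / 3)
        assert s.values[0, 0] == 1.0

    def test_sorensen_disjoint_zero(self):
        s = sorensen_similarity(ct([[1, 0], [0, 1]]))
        assert s.values[0, 1] == 0

    def test_metric_axioms_random(self, rng):
        table = ct((rng.integers(0, 20, size=(6, 30)) * rng.integers(0, 2, size=(6, 30))).tolist())
        for d in (bray_curtis(table), sorensen_similarity(table)):
            v = d.values
            assert np.allclose(v, v.T)
            assert (v >= -1e-12).all() and (v <= 1 + 1e-12).all()
            expected_diag = 1.0 if d.is_similarity else 0.0
            assert np.allclose(np.diag(v), expected_diag)


@pytest.fixture
def permanova_fixture():
    """Within-pair distance 1, cross distances 2, groups (A,A,B,B)."""
    d = np.full((4, 4), 2.0)
    d[0, 1] = d[1, 0] = 1.0
    d[2, 3] = d[3, 2] = 1.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(["s1", "s2", "s3", "s4"], d, "bray_curtis")


class TestPermanova:
    def test_exhaustive_enumeration_oracle(self, permanova_fixture):
        res = permanova(permanova_fixture, ["A", "A", "B", "B"], n_permutations=999, seed=0)
        assert res.exhaustive
        assert res.pseudo_f == pytest.approx(7.0)
        assert res.r2 == pytest.approx(7 / 9, abs=1e-4)
        assert res.p_value == pytest.approx(1 / 3)

    def test_all_equal_distances_p_high(self):
        d = np.full((6, 6), 1.0)
        np.fill_diagonal(d, 0.0)
        dm = DistanceMatrix([f"s{i}" for i in range(6)], d, "bray_curtis")
        res = permanova(dm, ["A"] * 3 + ["B"] * 3, seed=0)
        assert res.p_value == 1.0

    def test_label_order_invariance(self, rng):
        x = rng.normal(size=(8, 5))
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(x))
        labels = [f"s{i}" for i in range(8)]
        dm = DistanceMatrix(labels, d, "euclidean")
        groups = ["A", "B", "A", "B", "A", "B", "A", "B"]
        r1 = permanova(dm, groups, seed=1)
        perm = rng.permutation(8)
        dm2 = DistanceMatrix([labels[i] for i in perm], d[np.ix_(perm, perm)], "euclidean")
        r2 = permanova(dm2, [groups[i] for i in perm], seed=1)
        assert r1.pseudo_f == pytest.approx(r2.pseudo_f)
        assert r1.r2 == pytest.approx(r2.r2)

    def test_exhaustive_matches_monte_carlo_limit(self, rng):
        x = np.concatenate([rng.normal(0, 1, 3), rng.normal(2, 1, 3)])
        d = np.abs(x[:, None] - x[None, :])
        dm = DistanceMatrix([f"s{i}" for i in range(6)], d, "euclidean")
        groups = ["A"] * 3 + ["B"] * 3
        exact = permanova(dm, groups, n_permutations=10**6, seed=0)  # 20 distinct partitions
        assert exact.exhaustive
        mc = permanova(dm, groups, n_permutations=9, seed=3)  # forces Monte-Carlo path
        assert not mc.exhaustive
        mc_large = permanova(dm, groups, n_permutations=20, seed=4)
        assert mc_large.exhaustive  # auto-switches at the enumeration bound
        assert abs(mc_large.p_value - exact.p_value) < 1e-12

    def test_single_member_group_rejected(self, permanova_fixture):
        with pytest.raises(ValueError):
            permanova(permanova_fixture, ["A", "B", "B", "B"])


class TestNMDS:
    def test_euclidean_configuration_recovered(self, rng):
        pts = rng.normal(size=(10, 2))
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(pts))
        dm = DistanceMatrix([f"s{i}" for i in range(10)], d, "euclidean")
        coords, stress = nmds(dm, k=2, n_restarts=4, seed=0)
        assert stress < 0.01
        # recovered rank order of distances equals the input rank order
        emb = pdist(coords.to_numpy())
        from scipy.stats import spearmanr

        rho, _ = spearmanr(pdist(pts), emb)
        assert rho > 0.99

    def test_k_too_large_rejected(self, permanova_fixture):
        with pytest.raises(ValueError):
            nmds(permanova_fixture, k=3)


class TestQuadraticFit:
    def test_exact_parabola_recovery(self):
        x = np.linspace(0, 8, 30)
        y = 10 - (x - 4.0) ** 2
        fit = quadratic_fit(x, y)
        assert fit.shape == "hump"
        assert fit.peak_x == pytest.approx(4.0)
        assert fit.r2 == pytest.approx(1.0)

    def test_linear_data_classified_monotone(self):
        x = np.linspace(0, 10, 25)
        fit = quadratic_fit(x, x.copy())
        assert fit.shape == "monotone"
        assert abs(fit.b2) < 1e-10

    def test_noisy_hump_peak_recovered(self, rng):
        peaks = []
        for _ in range(100):
            x = rng.uniform(0, 8, 60)
            y = 10 - (x - 4.0) ** 2 + rng.normal(0, 0.5, 60)
            peaks.append(quadratic_fit(x, y).peak_x)
        assert np.mean(peaks) == pytest.approx(4.0, abs=0.5)

    def test_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            quadratic_fit([1, 1, 1, 1], [1, 2, 3, 4])


class TestGroupCompare:
    def test_pooled_t_matches_hand_calc(self):
        # classical pooled two-sample t on a small table
        a = np.array([5.0, 6.0, 7.0])
        b = np.array([8.0, 9.0, 10.0])
        res = group_compare(np.concatenate([a, b]), ["A"] * 3 + ["B"] * 3, "t_test")
        sp2 = (a.var(ddof=1) * 2 + b.var(ddof=1) * 2) / 4
        t_hand = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert res["statistic"] == pytest.approx(t_hand)

    def test_identical_groups_p_near_one(self):
        res = group_compare([1.0, 2.0, 3.0, 1.0, 2.0, 3.0], ["A"] * 3 + ["B"] * 3, "t_test")
        assert res["p_value"] == pytest.approx(1.0)

    def test_anova_matches_brute_force_sums_of_squares(self, rng):
        groups = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
        values = rng.normal(size=12) + np.repeat([0, 1, 2], 4)
        res = group_compare(values, groups, "anova_lsd")
        grand = values.mean()
        ss_between = sum(4 * (values[i * 4:(i + 1) * 4].mean() - grand) ** 2 for i in range(3))
        ss_within = sum(
            ((values[i * 4:(i + 1) * 4] - values[i * 4:(i + 1) * 4].mean()) ** 2).sum()
            for i in range(3)
        )
        f_hand = (ss_between / 2) / (ss_within / 9)
        assert res["statistic"] == pytest.approx(f_hand)
        assert len(res["pairwise_p"]) == 3


class TestCorrelate:
    @pytest.mark.parametrize(
        "method,transform,expected",
        [("pearson", lambda v: v, 1.0), ("spearman", lambda v: -v, -1.0)],
    )
    def test_perfect_monotone(self, method, transform, expected):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        r, _ = correlate(x, transform(x**2 if method == "spearman" else x), method)
        assert r == pytest.approx(expected)

    def test_pearson_closed_form(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 3.0])
        r_hand = np.sum((x - x.mean()) * (y - y.mean())) / math.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        r, _ = correlate(x, y, "pearson")
        assert r == pytest.approx(r_hand)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate([1, 1, 1], [1, 2, 3])


def test_chla_levels_half_open_bins():
    levels = chla_level([0.0, 1.9, 2.0, 4.9, 5.0, 10.9, 11.0])
    assert list(levels) == ["low", "low", "mid", "mid", "high", "high", "high"]
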