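from itertools import permutations

import numpy as np
import pytest

from seedbox.errors import (
    ConfigurationError,
    DomainError,
    InsufficientReplicationError,
)
from seedbox.stats import (
    correlate,
    holm_adjust,
    many_to_one,
    pairwise_tests,
    pcoa,
    permanova,
)


def anova_pseudo_f_oracle(points, labels):
    """Independent oracle: for Euclidean distances the PERMANOVA pseudo-F
    equals the classical multivariate ANOVA F computed from group centroids."""
    pts = np.asarray(points, float)
    labels = np.asarray(labels)
    levels = np.unique(labels)
    grand = pts.mean(axis=0)
    ssb = sum(
        (labels == lv).sum() * ((pts[labels == lv].mean(axis=0) - grand) ** 2).sum()
        for lv in levels
    )
    ssw = sum(
        ((pts[labels == lv] - pts[labels == lv].mean(axis=0)) ** 2).sum() for lv in levels
    )
    k, n = len(levels), len(pts)
    return (ssb / (k - 1)) / (ssw / (n - k))


class TestCorrelate:
    def test_perfect_linearity_pearson(self):
        x = np.arange(10.0)
        res = correlate(x, 2 * x + 1, method="pearson")
        assert res.statistic == pytest.approx(1.0)
        assert res.statistic_kind == "r"

    def test_monotone_nonlinear_spearman(self):
        x = np.arange(1.0, 11.0)
        res = correlate(x, np.exp(x), method="spearman")
        assert res.statistic == pytest.approx(1.0)
        assert res.statistic_kind == "rho"

    def test_midrank_oracle(self):
        # fixed 10-pair set with ties; oracle = Pearson on midranks
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0, 2.0, 6.0, 5.0, 3.0])
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.0, 8.0, 1.0, 8.0, 2.0, 8.0])

        def midranks(v):
            order = np.argsort(v, kind="stable")
            ranks = np.empty(len(v))
            i = 0
            sv = v[order]
            while i < len(v):
                j = i
                while j < len(v) and sv[j] == sv[i]:
                    j += 1
                ranks[order[i:j]] = (i + j + 1) / 2.0
                i = j
            return ranks

        rx, ry = midranks(x), midranks(y)
        expected = np.corrcoef(rx, ry)[0, 1]
        res = correlate(x, y, method="spearman")
        assert res.statistic == pytest.approx(expected, abs=1e-12)

    def test_pairwise_deletion(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0])
        y = np.array([2.0, 4.0, 6.0, 8.0, np.nan])
        res = correlate(x, y, method="pearson")
        assert res.df_or_n == 3 and res.statistic == pytest.approx(1.0)

    def test_too_few_pairs(self):
        with pytest.raises(DomainError):
            correlate([1.0, 2.0], [3.0, 4.0])

    def test_constant_vector_missing(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="seedbox.stats"):
            res = correlate([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
        assert res.statistic is None and res.p_value is None

    def test_unknown_method(self):
        with pytest.raises(ConfigurationError):
            correlate([1, 2, 3], [1, 2, 3], method="kendall")


class TestPermanova:
    def test_separated_clusters_minimal_p(self, rng):
        a = rng.normal(0, 0.05, size=(10, 3))
        b = rng.normal(8, 0.05, size=(10, 3))
        pts = np.vstack([a, b])
        labels = np.array(["a"] * 10 + ["b"] * 10)
        res = permanova(pts, labels, n_perm=999, seed=0)
        assert res.p_value == pytest.approx(1 / 1000)
        assert res.statistic_kind == "pseudoF"

    def test_pseudo_f_matches_anova_oracle(self, rng):
        pts = rng.normal(size=(12, 3))
        labels = np.repeat(["a", "b", "c"], 4)
        res = permanova(pts, labels, n_perm=99, seed=0)
        assert res.statistic == pytest.approx(anova_pseudo_f_oracle(pts, labels), abs=1e-9)

    def test_exact_enumeration_toy(self, rng):
        pts = rng.normal(size=(6, 3))
        labels = np.array(["a", "a", "a", "b", "b", "b"])
        res = permanova(pts, labels, exact=True)
        # independent exhaustive oracle over all 6! orderings
        d = pts[:, None, :] - pts[None, :, :]
        f_obs = anova_pseudo_f_oracle(pts, labels)
        count = 0
        total = 0
        for perm in permutations(range(6)):
            f_p = anova_pseudo_f_oracle(pts, labels[list(perm)])
            total += 1
            if f_p >= f_obs - 1e-12:
                count += 1
        assert res.statistic == pytest.approx(f_obs, abs=1e-9)
        assert res.p_value == pytest.approx(count / total, abs=1e-12)
        assert res.p_value > 0

    def test_rigid_motion_invariance(self, rng):
        pts = rng.normal(size=(12, 3))
        labels = np.repeat(["a", "b", "c"], 4)
        theta = 0.7
        rot = np.array(
            [
                [np.cos(theta), -np.sin(theta), 0],
                [np.sin(theta), np.cos(theta), 0],
                [0, 0, 1],
            ]
        )
        moved = pts @ rot.T + np.array([5.0, -3.0, 2.0])
        f1 = permanova(pts, labels, n_perm=99, seed=1).statistic
        f2 = permanova(moved, labels, n_perm=99, seed=1).statistic
        assert f1 == pytest.approx(f2, abs=1e-9)

    def test_seeded_determinism(self, rng):
        pts = rng.normal(size=(15, 3))
        labels = np.repeat(["a", "b", "c"], 5)
        r1 = permanova(pts, labels, n_perm=199, seed=42)
        r2 = permanova(pts, labels, n_perm=199, seed=42)
        assert r1.p_value == r2.p_value

    def test_seed_difference_within_mc_error(self, rng):
        pts = np.vstack([rng.normal(0, 1, (10, 3)), rng.normal(0.8, 1, (10, 3))])
        labels = np.array(["a"] * 10 + ["b"] * 10)
        p1 = permanova(pts, labels, n_perm=9999, seed=1).p_value
        p2 = permanova(pts, labels, n_perm=9999, seed=2).p_value
        # binomial MC error at B = 9999
        se = np.sqrt(p1 * (1 - p1) / 9999)
        assert abs(p1 - p2) < 5 * se + 2e-4

    def test_insufficient_replication(self, rng):
        pts = rng.normal(size=(4, 3))
        with pytest.raises(InsufficientReplicationError):
            permanova(pts, np.array(["a", "a", "a", "b"]), n_perm=99)
        with pytest.raises(InsufficientReplicationError):
            permanova(pts, np.array(["a"] * 4), n_perm=99)

    def test_n_perm_floor(self, rng):
        pts = rng.normal(size=(6, 3))
        with pytest.raises(ConfigurationError):
            permanova(pts, np.repeat(["a", "b"], 3), n_perm=10)

    def test_p_value_form(self, rng):
        pts = rng.normal(size=(10, 3))
        labels = np.repeat(["a", "b"], 5)
        res = permanova(pts, labels, n_perm=99, seed=3)
        assert res.p_value > 0
        assert (res.p_value * 100) == pytest.approx(round(res.p_value * 100))


class TestPairwise:
    def test_three_levels_three_results(self, rng):
        pts = rng.normal(size=(15, 3))
        labels = np.repeat(["a", "b", "c"], 5)
        results = pairwise_tests(pts, labels, n_perm=99, seed=0)
        assert len(results) == 3
        assert {r.label for r in results} == {"a vs b", "a vs c", "b vs c"}

    def test_t_is_sqrt_two_group_f(self, rng):
        pts = rng.normal(size=(10, 3))
        labels = np.repeat(["a", "b"], 5)
        res = pairwise_tests(pts, labels, n_perm=99, seed=0)[0]
        assert res.statistic == pytest.approx(
            np.sqrt(anova_pseudo_f_oracle(pts, labels)), abs=1e-9
        )

    def test_separated_minimal_p(self, rng):
        pts = np.vstack([rng.normal(0, 0.05, (10, 3)), rng.normal(9, 0.05, (10, 3))])
        labels = np.repeat(["a", "b"], 10)
        res = pairwise_tests(pts, labels, n_perm=999, seed=0)[0]
        assert res.p_value == pytest.approx(1 / 1000)

    def test_adjusted_at_least_raw(self, rng):
        pts = rng.normal(size=(15, 3))
        labels = np.repeat(["a", "b", "c"], 5)
        for r in pairwise_tests(pts, labels, n_perm=199, seed=0):
            assert r.p_adjusted >= r.p_value
            assert r.adjustment_method == "holm"

    def test_null_self_comparison_calibration(self, rng):
        # a level against a bootstrap copy of itself: adjusted p rarely small
        ok = 0
        for i in range(200):
            base = rng.normal(size=(8, 3))
            boot = base[rng.integers(0, 8, size=8)] + rng.normal(0, 1e-9, (8, 3))
            pts = np.vstack([base, boot])
            labels = np.repeat(["a", "b"], 8)
            res = pairwise_tests(pts, labels, n_perm=99, seed=i)[0]
            ok += res.p_adjusted > 0.05
        assert ok >= 188  # >= 94% of 200


class TestHolm:
    def test_against_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        p = [0.01, 0.04, 0.03, 0.005, 0.2, 0.9]
        _, adj, _, _ = multipletests(p, method="holm")
        assert holm_adjust(p) == pytest.approx(list(adj), abs=1e-12)

    def test_monotone_and_capped(self):
        adj = holm_adjust([0.5, 0.6, 0.9])
        assert all(0 < a <= 1 for a in adj)


class TestManyToOne:
    def test_identical_to_check_not_flagged(self):
        vals = {"TN1": [0.1, 0.12, 0.11], "A": [0.1, 0.12, 0.11]}
        res = many_to_one(vals, "TN1", n_perm=199, seed=0)
        assert len(res) == 1 and not res[0].flagged

    def test_direction_gates_flag(self, rng):
        vals = {
            "TN1": list(rng.normal(0.0, 0.01, 21)),
            "worse": list(rng.normal(-0.5, 0.01, 3)),
            "better": list(rng.normal(0.5, 0.01, 3)),
        }
        res = {r.label: r for r in many_to_one(vals, "TN1", n_perm=9999, seed=0)}
        assert res["better"].flagged
        assert not res["worse"].flagged  # wrong side, despite tiny p

    def test_missing_check(self):
        with pytest.raises(ConfigurationError):
            many_to_one({"A": [1, 2, 3]}, "TN1")

    def test_insufficient_values(self):
        with pytest.raises(InsufficientReplicationError):
            many_to_one({"TN1": [1.0], "A": [1.0, 2.0]}, "TN1")
        with pytest.raises(InsufficientReplicationError):
            many_to_one({"TN1": [1.0, 2.0], "A": [1.0]}, "TN1")

    def test_p_value_form_and_determinism(self, rng):
        vals = {"TN1": list(rng.normal(size=21)), "A": list(rng.normal(size=3))}
        r1 = many_to_one(vals, "TN1", n_perm=199, seed=5)[0]
        r2 = many_to_one(vals, "TN1", n_perm=199, seed=5)[0]
        assert r1.p_value == r2.p_value
        assert r1.p_value > 0 and (r1.p_value * 200) == pytest.approx(round(r1.p_value * 200))


class TestPcoa:
    def test_all_identical_points(self):
        d = np.zeros((4, 4))
        coords, evals = pcoa(d)
        assert np.allclose(coords, 0.0)

    def test_two_points_symmetry(self):
        d = np.array([[0.0, 2.5], [2.5, 0.0]])
        coords, _ = pcoa(d)
        axis1 = sorted(coords[:, 0])
        assert axis1 == pytest.approx([-1.25, 1.25], abs=1e-9)

    def test_reconstruction_oracle(self, rng):
        pts = rng.normal(size=(10, 3))
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        coords, evals = pcoa(d)
        d2 = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1))
        assert np.abs(d - d2).max() < 1e-9
        assert (np.diff(evals) <= 1e-9).all()  # ordered by eigenvalue

    def test_asymmetric_raises(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(DomainError):
            pcoa(d)

    def test_nonzero_diagonal_raises(self):
        d = np.array([[1.0, 1.0], [1.0, 0.0]])
        with pytest.raises(DomainError):
            pcoa(d)
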