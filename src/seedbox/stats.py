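"""Correlation and permutation-based inference on colour triplets.

The inferential layer deliberately replaces classical repeated-measures
GLMs and Duncan/Tukey post-hoc machinery with permutation analogues:

* PERMANOVA-style pseudo-F on the Euclidean distance matrix of
  (meanR, meanG, meanB) triplets, with free permutation of observations;
* pairwise two-level permutation tests (t-like statistic = sqrt of the
  two-group pseudo-F) with Holm adjustment;
* a many-to-one permutation comparison of every variety against the
  susceptible check (a permutation analogue of many-to-one post-hoc
  comparisons);
* unconstrained principal-coordinates ordination in place of constrained
  ordination, on the same distance matrix.

All permutation p-values have the form (b + 1) / (B + 1) and are never 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
from scipy import stats as sps
from scipy.spatial.distance import pdist, squareform

from ._rng import substream
from .errors import ConfigurationError, DomainError, InsufficientReplicationError

__all__ = [
    "TestResult",
    "correlate",
    "permanova",
    "pairwise_tests",
    "many_to_one",
    "pcoa",
    "holm_adjust",
]

import logging

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TestResult:
    statistic: float | None
    statistic_kind: str  # rho | r | pseudoF | tPairwise | meanDiff
    p_value: float | None
    n_permutations: int = 0
    df_or_n: tuple | int | None = None
    adjusted: bool = False
    adjustment_method: str | None = None
    p_adjusted: float | None = None
    label: str | None = None
    flagged: bool | None = None


def correlate(x, y, method: str = "spearman") -> TestResult:
    """Spearman (midranks for ties) or Pearson correlation with the
    t-approximation p-value; pairs with missing values are dropped."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise DomainError("x and y must be paired")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise DomainError(f"need >= 3 complete pairs, got {len(x)}")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        logger.warning("constant vector: correlation undefined")
        kind = "rho" if method == "spearman" else "r"
        return TestResult(None, kind, None, df_or_n=len(x))
    if method == "spearman":
        rho, p = sps.spearmanr(x, y)
        return TestResult(float(rho), "rho", float(p), df_or_n=len(x))
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
        return TestResult(float(r), "r", float(p), df_or_n=len(x))
    raise ConfigurationError(f"unknown correlation method {method!r}")


def _ss_within(d2: np.ndarray, groups: list[np.ndarray]) -> float:
    ssw = 0.0
    for idx in groups:
        ssw += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return ssw


def _pseudo_f(d2: np.ndarray, labels: np.ndarray, levels: np.ndarray) -> float:
    n = len(labels)
    k = len(levels)
    groups = [np.flatnonzero(labels == lv) for lv in levels]
    sst = d2.sum() / (2.0 * n)
    ssw = _ss_within(d2, groups)
    ssb = sst - ssw
    return (ssb / (k - 1)) / (ssw / (n - k))


def _check_groups(labels: np.ndarray) -> np.ndarray:
    levels, counts = np.unique(labels, return_counts=True)
    if len(levels) < 2:
        raise InsufficientReplicationError("need at least 2 factor levels")
    bad = levels[counts < 2]
    if len(bad):
        raise InsufficientReplicationError(f"levels with < 2 observations: {list(bad)}")
    return levels


def permanova(
    points,
    labels,
    n_perm: int = 999,
    seed: int = 0,
    exact: bool = False,
) -> TestResult:
    """One-factor permutational multivariate ANOVA on Euclidean distances.

    pseudo-F = (SS_between / df_between) / (SS_within / df_within), with SS
    terms computed from the pairwise distance matrix. The p-value counts
    permuted statistics >= the observed one: (b + 1) / (B + 1). With
    ``exact=True`` all distinct label orderings are enumerated instead
    (only sensible for n <= 9).
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    labels = np.asarray(labels)
    if len(pts) != len(labels):
        raise DomainError("points and labels must have equal length")
    levels = _check_groups(labels)
    if not exact and n_perm < 99:
        raise ConfigurationError(f"n_perm must be >= 99, got {n_perm}")
    d2 = squareform(pdist(pts, metric="euclidean")) ** 2
    f_obs = _pseudo_f(d2, labels, levels)
    n = len(labels)
    k = len(levels)
    if exact:
        if n > 9:
            raise ConfigurationError("exact enumeration limited to n <= 9")
        b = 0
        total = 0
        for perm in permutations(range(n)):
            f_p = _pseudo_f(d2, labels[list(perm)], levels)
            total += 1
            if f_p >= f_obs - 1e-12:
                b += 1
        p = b / total  # identity permutation is in the enumeration: p > 0
        return TestResult(float(f_obs), "pseudoF", float(p), n_permutations=total - 1,
                          df_or_n=(k - 1, n - k))
    rng = substream(seed, "permanova")
    b = 0
    for _ in range(n_perm):
        f_p = _pseudo_f(d2, labels[rng.permutation(n)], levels)
        if f_p >= f_obs - 1e-12:
            b += 1
    p = (b + 1) / (n_perm + 1)
    return TestResult(float(f_obs), "pseudoF", float(p), n_permutations=n_perm,
                      df_or_n=(k - 1, n - k))


def holm_adjust(p_values: list[float]) -> list[float]:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    m = len(p_values)
    order = np.argsort(p_values)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * p_values[i])
        adj[i] = min(running, 1.0)
    return adj.tolist()


def pairwise_tests(
    points, labels, n_perm: int = 999, seed: int = 0, adjustment: str = "holm"
) -> list[TestResult]:
    """Two-level permutation test for every unordered pair of factor levels.

    The statistic is sqrt of the two-group pseudo-F (a t-like quantity);
    raw and Holm-adjusted p-values are reported.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=np.float64))
    labels = np.asarray(labels)
    levels = _check_groups(labels)
    results = []
    for i, (a, bl) in enumerate(combinations(levels, 2)):
        sel = (labels == a) | (labels == bl)
        res = permanova(pts[sel], labels[sel], n_perm=n_perm, seed=seed + i)
        results.append(
            TestResult(
                statistic=float(np.sqrt(res.statistic)),
                statistic_kind="tPairwise",
                p_value=res.p_value,
                n_permutations=n_perm,
                df_or_n=res.df_or_n,
                label=f"{a} vs {bl}",
            )
        )
    raw = [r.p_value for r in results]
    adj = holm_adjust(raw) if adjustment == "holm" else (
        [min(p * len(raw), 1.0) for p in raw] if adjustment == "bonferroni" else raw
    )
    return [
        TestResult(
            statistic=r.statistic,
            statistic_kind=r.statistic_kind,
            p_value=r.p_value,
            n_permutations=r.n_permutations,
            df_or_n=r.df_or_n,
            adjusted=adjustment != "none",
            adjustment_method=adjustment,
            p_adjusted=a,
            label=r.label,
        )
        for r, a in zip(results, adj)
    ]


def _perm_mean_diff_p(a: np.ndarray, b: np.ndarray, n_perm: int, rng: np.random.Generator) -> float:
    """Two-sided permutation p for the difference of group means."""
    obs = abs(a.mean() - b.mean())
    pool = np.concatenate([a, b])
    na = len(a)
    # vectorized: one independent shuffle of the pooled values per row
    perm = rng.permuted(np.tile(pool, (n_perm, 1)), axis=1)
    diffs = np.abs(perm[:, :na].mean(axis=1) - perm[:, na:].mean(axis=1))
    b_count = int((diffs >= obs - 1e-12).sum())
    return (b_count + 1) / (n_perm + 1)


def many_to_one(
    values: dict[str, np.ndarray | list],
    check: str,
    n_perm: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
    direction: str = "greater",
    adjustment: str = "holm",
) -> list[TestResult]:
    """Permutation analogue of many-to-one post-hoc comparisons.

    Each variety's replicate values are compared against the susceptible
    check with a two-sided permutation test on the mean difference; p-values
    are Holm-adjusted across varieties. A variety is flagged as less damaged
    than the check when its adjusted p <= alpha and its mean lies on the
    better-condition side (``direction='greater'`` for indices where larger
    means healthier, ``'less'`` for the reverse).
    """
    if check not in values:
        raise ConfigurationError(f"check {check!r} missing from values")
    if direction not in {"greater", "less"}:
        raise ConfigurationError(f"direction must be 'greater' or 'less', got {direction!r}")
    check_vals = np.asarray(values[check], dtype=np.float64)
    if len(check_vals) < 2:
        raise InsufficientReplicationError("check needs >= 2 replicate values")
    names = [k for k in values.keys() if k != check]
    raw: list[float] = []
    stats_: list[float] = []
    for i, name in enumerate(names):
        v = np.asarray(values[name], dtype=np.float64)
        if len(v) < 2:
            raise InsufficientReplicationError(f"variety {name!r} needs >= 2 replicate values")
        rng = substream(seed, "many_to_one", name)
        stats_.append(float(v.mean() - check_vals.mean()))
        raw.append(_perm_mean_diff_p(v, check_vals, n_perm, rng))
    adj = holm_adjust(raw) if adjustment == "holm" else (
        [min(p * len(raw), 1.0) for p in raw] if adjustment == "bonferroni" else raw
    )
    results = []
    for name, st, p, pa in zip(names, stats_, raw, adj):
        better = st > 0 if direction == "greater" else st < 0
        results.append(
            TestResult(
                statistic=st,
                statistic_kind="meanDiff",
                p_value=p,
                n_permutations=n_perm,
                df_or_n=(len(values[name]), len(check_vals)),
                adjusted=adjustment != "none",
                adjustment_method=adjustment,
                p_adjusted=pa,
                label=name,
                flagged=bool(pa <= alpha and better),
            )
        )
    return results


def pcoa(distance_matrix) -> tuple[np.ndarray, np.ndarray]:
    """Principal-coordinates ordination of a symmetric distance matrix.

    Returns (coordinates, eigenvalues): Gower-centred double-centering of
    -0.5 * D^2 followed by an eigendecomposition; axes are ordered by
    decreasing eigenvalue and only non-negligible positive axes are kept.
    """
    d = np.asarray(distance_matrix, dtype=np.float64)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise DomainError("distance matrix must be square")
    if not np.allclose(d, d.T, atol=1e-10):
        raise DomainError("distance matrix must be symmetric")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise DomainError("distance matrix must have a zero diagonal")
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (d**2) @ j
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-10, 1e-10 * max(abs(evals[0]), 1.0)) if n else 0.0
    keep = evals > tol
    coords = evecs[:, keep] * np.sqrt(evals[keep])
    if coords.shape[1] == 0:
        coords = np.zeros((n, 1))
        evals = np.zeros(1)
        return coords, evals
    return coords, evals[keep]
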