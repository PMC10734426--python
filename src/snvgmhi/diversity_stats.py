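"""Alpha/beta diversity, ordination, permutation tests and alpha-matched
group comparison.

PERMANOVA follows the one-factor adonis construction: the pseudo-F is
computed from the among/within sum-of-squares decomposition of the
squared distance matrix, and the p-value from seeded label permutations,
``p = (1 + #{F_perm >= F_obs}) / (1 + n_perm)`` with 999 permutations by
default.  Alpha-matched comparison pairs healthy with nonhealthy samples
whose alpha diversity differs by at most a tolerance (0.01 for Shannon,
0.001 for Simpson in the source analysis) and applies the Wilcoxon
signed-rank test to the paired quantity of interest.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.stats


def _proportions(vector) -> np.ndarray:
    v = np.asarray(vector, dtype=float)
    if (v < 0).any():
        raise ValueError("negative entries in abundance vector")
    total = v.sum()
    if total <= 0:
        raise ValueError("all-zero vector: diversity undefined")
    return v / total


def shannon(vector) -> float:
    """Shannon index, natural log, on renormalized proportions."""
    p = _proportions(vector)
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def simpson(vector) -> float:
    """Gini-Simpson index ``1 - sum(p_i^2)``."""
    p = _proportions(vector)
    return float(1.0 - (p ** 2).sum())


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity ``sum|x-y| / sum(x+y)`` in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("Bray-Curtis requires nonnegative vectors")
    denom = (x + y).sum()
    if denom == 0:
        raise ValueError("both vectors all-zero: Bray-Curtis undefined")
    return float(np.abs(x - y).sum() / denom)


def euclidean(x, y) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("length mismatch")
    return float(np.linalg.norm(x - y))


@dataclass
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray
    metric: str

    def __post_init__(self):
        d = np.asarray(self.values, dtype=float)
        if d.ndim != 2 or d.shape[0] != d.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(d, d.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0, atol=1e-10):
            raise ValueError("distance matrix diagonal must be zero")
        self.values = d


def distance_matrix(table, sample_ids: Sequence[str],
                    metric: str = "bray_curtis") -> DistanceMatrix:
    """Pairwise distances over the rows of ``table`` (samples x features)."""
    fn = {"bray_curtis": bray_curtis, "euclidean": euclidean}[metric]
    X = np.asarray(table, dtype=float)
    n = X.shape[0]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = fn(X[i], X[j])
    return DistanceMatrix(sample_ids=list(sample_ids), values=d, metric=metric)


@dataclass
class PcoaResult:
    coordinates: np.ndarray             # samples x axes (positive eigenvalues)
    eigenvalues: np.ndarray             # all, descending, negatives included
    explained: np.ndarray               # fraction of positive-eigenvalue sum


def pcoa(dm: DistanceMatrix) -> PcoaResult:
    """Classical metric MDS: eigendecomposition of the double-centered
    ``-0.5 * D^2`` matrix.  Negative eigenvalues are reported, not clipped;
    coordinates are returned only for positive eigenvalues."""
    d = dm.values
    n = d.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (d ** 2) @ J
    evals, evecs = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    pos = evals > 1e-10
    coords = evecs[:, pos] * np.sqrt(evals[pos])
    explained = (evals[pos] / evals[pos].sum()) if pos.any() else np.array([])
    return PcoaResult(coordinates=coords, eigenvalues=evals,
                      explained=explained)


def permanova(dm: DistanceMatrix, labels: Sequence[str],
              n_perm: int = 999, seed: int | None = None
              ) -> tuple[float, float, float]:
    """One-factor PERMANOVA: returns ``(R2, pseudo_F, p)``.

    ``SS_total = sum(d_ij^2)/n`` over i<j; within-group SS analogously per
    group; ``F = (SS_A/(a-1)) / (SS_W/(n-a))``.  The p-value uses seeded
    label permutations with the add-one rule.
    """
    labels = np.asarray(labels)
    d2 = dm.values ** 2
    n = len(labels)
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if (counts < 2).any():
        raise ValueError("each group needs at least two samples")
    a = len(groups)
    iu = np.triu_indices(n, 1)
    ss_total = d2[iu].sum() / n

    def ss_within(lab):
        ss = 0.0
        for g in groups:
            idx = np.flatnonzero(lab == g)
            sub = d2[np.ix_(idx, idx)]
            ss += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
        return ss

    ssw = ss_within(labels)
    ssa = ss_total - ssw
    f_obs = (ssa / (a - 1)) / (ssw / (n - a))
    r2 = ssa / ss_total

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(labels)
        ssw_p = ss_within(perm)
        f_p = ((ss_total - ssw_p) / (a - 1)) / (ssw_p / (n - a))
        if f_p >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return float(r2), float(f_obs), float(p)


@dataclass
class MatchedPairSet:
    pairs: list[tuple[str, str, float]]     # (healthy id, nonhealthy id, |d|)
    tolerance: float
    matched_fraction: float


def match_pairs(alpha_values: dict[str, float], labels: dict[str, str],
                tolerance: float) -> MatchedPairSet:
    """Greedy cross-group matching on alpha diversity.

    All healthy x nonhealthy pairs are sorted by absolute alpha difference
    (ties broken by sample ids for determinism) and accepted while both
    members are unused and the difference is within ``tolerance``.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    healthy = sorted(s for s, g in labels.items() if g == "healthy")
    nonhealthy = sorted(s for s, g in labels.items() if g == "nonhealthy")
    candidates = sorted(
        ((abs(alpha_values[h] - alpha_values[n]), h, n)
         for h in healthy for n in nonhealthy),
        key=lambda t: (t[0], t[1], t[2]))
    used: set[str] = set()
    pairs = []
    for diff, h, n in candidates:
        if diff > tolerance:
            break
        if h in used or n in used:
            continue
        used.add(h)
        used.add(n)
        pairs.append((h, n, diff))
    denom = len(healthy) + len(nonhealthy)
    frac = (2 * len(pairs) / denom) if denom else 0.0
    return MatchedPairSet(pairs=pairs, tolerance=tolerance,
                          matched_fraction=frac)


def wilcoxon_signed_rank(differences) -> float:
    """Two-sided Wilcoxon signed-rank p on paired differences.

    Exact distribution for n <= 25 without ties or zeros, normal
    approximation with continuity correction otherwise.
    """
    d = np.asarray(differences, dtype=float)
    d = d[d != 0]
    if len(d) == 0:
        raise ValueError("all differences zero: test undefined")
    exact_ok = len(d) <= 25 and len(np.unique(np.abs(d))) == len(d)
    method = "exact" if exact_ok else "approx"
    res = scipy.stats.wilcoxon(d, alternative="two-sided", method=method,
                               correction=(method == "approx"))
    return float(res.pvalue)


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum p (tie-corrected)."""
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.pvalue)
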